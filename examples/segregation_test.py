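"""Two-locus segregation analysis of an F2 plumage-count table.

Enumerates the epistasis model's expected 3:6:3:4 class ratio, compares it
with observed counts from a 1,281-bird F2 cohort, and runs the Pearson
goodness-of-fit test.  A high p-value means the counts are compatible with
two unlinked loci, one epistatic and one incompletely dominant.
"""

from plumagemap import mendel

observed = {"BF": 235, "GF": 452, "WB": 234, "WY": 360}

ratio = mendel.enumerate_f2_ratio()
real, ints = mendel.expected_counts(sum(observed.values()), ratio)
anchored = mendel.observed_ratio(observed, "BF")
gof = mendel.chisq_gof(observed, ratio)

print("class  observed  expected  int  obs-ratio  model-ratio")
for k in ("BF", "GF", "WB", "WY"):
    print(f"{k:5s} {observed[k]:9d} {real[k]:9.2f} {ints[k]:4d} {anchored[k]:10.1f} {float(ratio[k]) * 16:8.0f}/16")
print(f"\nPearson chi2 = {gof.chi2:.3f} (df {gof.df}), p = {gof.p:.3f}")
print("p > 0.05: the counts fit the two-locus epistasis model.")
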