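"""Windowed read-depth CNV genotyping with a planted duplication.

Simulates 1,000-bp window read counts for a founder panel with a
heterozygous duplication (3 copies) planted in one breed, normalizes depth
against the other breed as reference, and classifies each window into the
copy-number classes 0 / 0.5 / 1 / 1.5 / 2 / complex.
"""

import numpy as np

from plumagemap import cnv, cross_sim

layout = cross_sim.GenomeLayout(
    chromosomes=(("chr13", 2_000_000), ("chr33", 1_000_000)),
    snp_positions={"chr13": np.array([1_000_000]), "chr33": np.array([500_000])},
    recomb_rate=1.0,
)
panel = cross_sim.default_panel(
    layout, seed=2, causal_B=("chr13", 1_000_000), causal_R=("chr33", 500_000)
)
cohort = cross_sim.breed_cross(
    cross_sim.CrossConfig(layout=layout, founders=panel, n_per_founder=(20, 20), n_f1=0, n_f2=0, seed=3)
)

planted = [("chr33", 500_000, 520_000, {"LC": 3.0})]  # het duplication in LC
depth, _ = cross_sim.simulate_depth(cohort, planted, chroms=["chr33"], mean_depth=30, seed=4)
reference = [s for s in cohort.samples if s.startswith("PK")]
calls = cnv.call_cnvs(depth, cohort.samples, reference)

in_cnv = calls[(calls["start"] > 499_000) & (calls["end"] <= 520_000)]
lc, pk = in_cnv[in_cnv["sample"].str.startswith("LC")], in_cnv[in_cnv["sample"].str.startswith("PK")]
print("planted heterozygous duplication, chr33:500,000-520,000 (LC only):")
print(f"  LC mean depth ratio {lc['depth_ratio'].mean():.2f}, modal class {lc['cn_class'].mode().iloc[0]}")
print(f"  PK mean depth ratio {pk['depth_ratio'].mean():.2f}, modal class {pk['cn_class'].mode().iloc[0]}")
print("a ratio of 1.5 is a heterozygous duplication (3 copies); 1.0 is normal diploidy")
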