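# Methods

## The genetic model

Plumage colour is modelled by two unlinked autosomal loci. The *Bb* locus
gates melanin synthesis; *bb* is epistatic and yields white feathers with a
yellow beak (WY) whatever the second locus carries. On a *B_* background
the *Rr* locus controls feather melanin with incomplete dominance: *RR* →
black-feathered (BF), *Rr* → gray (GF), *rr* → white-feathered with black
beak (WB). `mendel.SegregationModel` encodes this map over the nine
(B-dosage, R-dosage) diplotypes; `enumerate_f2_ratio` derives the exact
rational class probabilities of a BbRr × BbRr intercross — 3:6:3:4 over 16
— by enumeration, so any alternative map (no epistasis, collapsed classes)
is handled by the same code path.

Expected counts are reported two ways: the real-valued E_k = n·p_k used in
all statistics, and an integer view that rounds half-away-from-zero and
then repairs the class with the largest fractional remainder so the
integers sum to n (at n = 1,281 this reproduces the conventional table
240 / 481 / 240 / 320, where plain rounding of 480.375 would give 480).
The goodness-of-fit test is Pearson's χ² against the real-valued E_k with
df = k − 1, the ratio being specified a priori; rounding the expectations
first would distort the statistic. For the widely quoted observed counts
235 : 452 : 234 : 360 this gives χ² = 6.881, p = 0.076 (df 3). Published
tabulations of these counts sometimes carry a smaller χ² that cannot be
reproduced from the stated inputs by the standard Pearson formula; this
package reports the standard value and makes no attempt to reverse-engineer
any other.

## The synthetic intercross

`cross_sim` emulates the statistical structure of a two-breed resequencing
panel rather than any particular dataset.

**Founders.** Two breeds with per-SNP alternate-allele frequencies: neutral
frequencies are drawn per breed from Beta(0.8, 0.8) truncated to
[0.05, 0.95]; a configurable fraction (default 10%) of SNPs are
ancestry-informative (0.02 vs 0.98 between breeds, random orientation) so
that ΔAF > 0.8 screens have genuine hits; the two causal loci are fixed
differences (ΔAF = 1) on different chromosomes, breed 0 being *BBrr* and
breed 1 *bbRR*. Founder genotypes are binomial(2, freq) via two Bernoulli
haplotypes. Noise-free ancestry painting, used by truth-recovery tests, is
obtained with informative frequencies (0, 1).

**Meiosis.** Haldane model, no interference: per chromosome the crossover
count is Poisson in the genetic length, breakpoints uniform in bp, and the
transmitted haplotype alternates parental origin at each breakpoint. Every
crossover position is recorded in the cohort truth, along with each
individual's causal diplotype; each F2 phenotype equals the model map
applied to its true diplotype by construction.

**Default study conditions.** Founder panel sizes 59 and 117 (the breed
proportions of the real panel being emulated), 100 F1 and 400 F2 (the real
cross produced ~1,260 F1 and 1,281 F2; the GWAS cohort held 188 segregants
— desk scale sits in between), genotype missingness 2% i.i.d., sex
Bernoulli(0.5) carried only as a covariate (the trait is autosomal).

**Default genome.** Six 60-Mb neutral chromosomes plus a 20-Mb "chr13"
(melanin-gate locus) and a 10-Mb "chr33" (feather-melanin locus at
5,303,994). SNPs are placed at uniform density (~14/Mb, ~5,500 markers), so
the causal chromosomes carry only a few percent of all markers, as in a
real genome. Recombination uses an obligate-crossover map: every
chromosome's genetic length is at least 0.5 Morgans, giving the small
chromosomes the high per-Mb rates characteristic of avian
microchromosomes. Both choices matter for fidelity at desk scale: with
equal per-chromosome marker counts or long-LD microchromosomes, a single
chromosome's founder ancestry dominates the relationship matrix and its
top principal components become that chromosome's causal-locus dosage —
an artifact a 33-chromosome genome does not have, and one that would make
the conditional re-scan unrepresentatively hard.

**Depth.** `simulate_depth` draws 1,000-bp window read counts as
Poisson(mean_depth × copy_number / 2 × library_factor), with planted CNVs
specified per breed; truth copy numbers are returned alongside.

**What the simulator does not model.** Sequence-level reads, alignment and
calling error, genotype-likelihood uncertainty, linkage disequilibrium
within founder breeds (founder SNPs are drawn independently given the
frequencies), selection, crossover interference, and sex chromosomes.
Passing tests therefore demonstrate the statistical machinery under the
stated generative model, not robustness to real-data artifacts such as
batch effects or reference bias.

`simulate_screen_panel` is a separate, fully synthetic candidate-region
generator for the cross-breed screen: it plants a causal SNP (optionally a
complete-LD twin and causal-like indels) whose genotypes are perfectly
concordant with phenotype across seven groups (two founder breeds, two
independent black-feathered validation breeds, three intercross classes),
plus decoys that each fail exactly one screen step.

## Association model

The scan fits y = Xb + g + e with g ~ N(0, σ²_g G) and e ~ N(0, σ²_e I),
where G is the genomic relationship matrix ZZᵀ/m from genotypes
mean-imputed per variant, centred by 2p̂ and scaled by √(2p̂(1−p̂))
(monomorphic variants skipped). Variance components are estimated once on
the null model by profiled REML over δ = σ²_e/σ²_g: one eigendecomposition
of G makes each profile evaluation O(n·p); a 100-point grid on log₁₀δ ∈
[−5, 5] brackets the optimum and a golden-section/Brent refinement
polishes it. Each variant is then tested by generalized least squares on
eigen-rotated, variance-whitened data with the components held fixed — the
EMMAX approximation — using the Wald statistic β²/se² against χ²(1).
P-values are floored at 1e-300 to keep −log₁₀p finite. With G = I the
profile is flat in δ (any split of the OLS residual variance is
equivalent); the scan then reduces exactly to ordinary regression, which
the tests verify. Variants collinear with the covariates, including
monomorphic ones, are reported as missing.

Fixed effects are an intercept, a sex indicator, and the top-3 principal
components of G (eigenvectors scaled by √eigenvalue, deterministic sign);
a conditional re-scan appends the conditioning variant's genotype to X and
reports that variant as missing. The genome-wide threshold is
−log₁₀(α/N); α = 0.01 with N = 8,887,194 gives 8.95, the value used at
full resequencing scale.

**Phenotype coding.** No canonical numeric coding exists for a two-locus
colour series; the default is an ordinal melanin dose WY=0 < WB=1 < GF=2 <
BF=3, which makes both loci detectable in one scan (the gate locus through
the large WY-vs-rest contrast, the feather locus through the within-*B_*
gradient). A restricted coding over black-beaked birds (WB=0, GF=1, BF=2)
is provided for fine-scans. Both are configuration, not claims about how
any particular study coded its trait.

## Divergence and fine-mapping

Per-SNP FST uses the Hudson estimator — numerator (p₁−p₂)² −
p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator p₁(1−p₂) + p₂(1−p₁) —
chosen for its robustness to unequal sample sizes in two-population
contrasts; Weir–Cockerham is available behind a flag. Windows are fixed
10-kb tiles from coordinate 1, half-open, scored as ratio-of-averages (sum
of numerators over sum of denominators), which downweights
low-information SNPs; empty windows are omitted and negative per-SNP
estimates are kept in the sums.

Ancestry painting assigns each individual, at every candidate-region SNP
with founder ΔAF > 0.8, the dosage of the founder-1-major allele: 2 →
homozygous founder 1, 1 → heterozygous, 0 → homozygous founder 2, missing
→ unknown. Breakpoints are reported as the open interval between the
flanking informative SNPs where the painted state changes (unknown states
carry over) — genotype data cannot localize a crossover more finely, so no
point estimate is ever produced. The region is cut at the union of the
cohort's breakpoint intervals (overlapping intervals merged; SNPs strictly
inside a merged cut are ancestry-ambiguous and belong to no block); block
consensus per individual requires ≥ 80% agreement of known member states.
Block–phenotype concordance is scored over black-beaked individuals only
(the feather locus is invisible under *bb*): WB ↔ homozygous founder 1,
GF ↔ heterozygous, BF ↔ homozygous founder 2, unknown counting as
mismatch; blocks scoring 1.0 are the candidate causal interval. An
optional 3-SNP majority-vote smoothing of the painted states (off by
default) absorbs isolated genotyping noise at the cost of displacing true
double-recombinants.

The causative screen runs three nested steps after excluding indels (which
are listed separately): (1) founder-contrast FST ≥ 0.8 — the boundary is
inclusive since the rule excludes variants *below* 0.8; (2) shared high
divergence, operationalized as the intersection of the top decile of FST
in every white-founder-vs-black-breed contrast (the fraction is
configurable; no published numeric rule exists for "highest shared");
(3) complete genotype–phenotype concordance — every validation-breed
individual must carry exactly the dosage of the white-founder allele its
phenotype class implies, zero exceptions. Surviving variants with pairwise
r² ≥ 0.999 are reported as one LD group. Empty survivors at any step
produce an empty final set, not an error.

## CNV classes

Window counts are scaled to a common library size (total-count
normalization), divided by the per-window median of a reference
population, and classified by nearest copy-number class in
{0, 0.5, 1, 1.5, 2} with boundaries at the midpoints (0.25, 0.75, 1.25,
1.75) and exact boundaries rounding up; ratios above 2.25 are complex
duplications. The median (rather than mean) reference aggregation is a
robustness choice. Only per-sample class calls are produced; population
CNV genotyping is out of scope.

## Expression utilities

CPM is count × 10⁶ / library size. Group log2 fold change uses a
pseudocount of 1 on the CPM means (no published pseudocount rule exists;
1 is the common default). qPCR relative expression is 2^−ΔΔCT with
technical replicates averaged before ΔCT; the calculation is invariant to
adding a constant to both target and reference CTs of a condition.

## Numerical and testing choices

Sizes used in the checked experiments: the GWAS recovery runs on ~5,400
SNPs with 400 F2 (seconds on one core); null calibration on 200 samples ×
2,000 SNPs with G = I; segregation convergence on an F2 of 10,000 from a
minimal two-chromosome genome; fine-mapping on 50 replicate 300-F2 cohorts
over a 0.4-Mb region with ~50 noise-free informative SNPs and an
exaggerated regional recombination rate (20 cM/Mb) so a short region
yields scoreable recombinants. Closed-form statistics (χ² GOF, GRM, Hudson
FST, LD r², CPM, 2^−ΔΔCT) are verified against independent brute-force
implementations to 1e-10 or better.

Known limitations: deterministic ancestry painting (no HMM posterior
decoding); no genotype likelihoods, phasing or imputation beyond the mean
imputation internal to the scan; no multi-locus or multi-trait association
models; no genomic-control correction; FST limited to two-population
contrasts; CNV calls are per-sample only. The identity-kinship REML ridge
is reported at the grid optimum rather than flagged.
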