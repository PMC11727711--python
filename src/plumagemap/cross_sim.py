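"""Synthetic F2 intercross simulator for the two-locus plumage model.

Emulates the statistical structure of a resequencing panel built from two
strongly diverged founder breeds — a Liancheng-like breed (*BBrr*: white
feathers, black beak) and a Pekin-like breed (*bbRR*: white feathers, yellow
beak) — crossed to F1 (all *BbRr*, gray-feathered) and intercrossed to F2,
where the four plumage classes segregate 3:6:3:4.

Founder haplotypes are drawn from per-breed allele frequencies; the two
planted causal loci are fixed for opposite alleles in the two breeds
(delta-AF = 1) and lie on different chromosomes.  Meioses follow a Haldane
(no-interference) model: crossover counts are Poisson in the chromosome's
genetic length, with breakpoint positions uniform in bp.  The full truth —
causal diplotypes, per-gamete crossover positions, pre-missingness
haplotypes — is retained so downstream inferences can be scored exactly.

Also provides windowed read-depth simulation for copy-number analysis and an
engineered candidate-region panel generator for the causative-variant screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mendel import SegregationModel
from .variant_io import VariantDataset

__all__ = [
    "GenomeLayout",
    "FounderPanel",
    "CrossConfig",
    "SimulatedCohort",
    "default_layout",
    "default_panel",
    "default_config",
    "simulate_founders",
    "make_gamete",
    "breed_cross",
    "simulate_depth",
    "simulate_screen_panel",
    "write_cohort",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, SNP positions and recombination rates.

    ``recomb_rate`` is in centimorgans per megabase, either a single genome
    -wide value or a per-chromosome mapping (avian microchromosomes have
    much higher per-Mb rates than macrochromosomes because every chromosome
    receives at least one crossover per meiosis).  Positions are 1-based.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: Mapping[str, np.ndarray]
    recomb_rate: float | Mapping[str, float] = 1.0

    def rate_of(self, chrom: str) -> float:
        if isinstance(self.recomb_rate, Mapping):
            return float(self.recomb_rate[chrom])
        return float(self.recomb_rate)

    def __post_init__(self) -> None:
        for chrom, _ in self.chromosomes:
            if self.rate_of(chrom) < 0:
                raise ValueError("recombination rate must be >= 0")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, pos in self.snp_positions.items():
            pos = np.asarray(pos)
            if name not in lengths:
                raise ValueError(f"positions given for unknown chromosome {name}")
            if len(pos) and (pos[0] < 1 or pos[-1] > lengths[name]):
                raise ValueError(f"positions out of bounds on {name}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {name}")

    @property
    def n_snps(self) -> int:
        return sum(len(self.snp_positions[c]) for c, _ in self.chromosomes)

    def chrom_slices(self) -> dict[str, slice]:
        """Slices into the flat (layout-ordered) variant axis, per chromosome."""
        out, start = {}, 0
        for name, _ in self.chromosomes:
            n = len(self.snp_positions[name])
            out[name] = slice(start, start + n)
            start += n
        return out

    def variant_frame(self) -> pd.DataFrame:
        rows = []
        for name, _ in self.chromosomes:
            for p in self.snp_positions[name]:
                rows.append((name, int(p)))
        df = pd.DataFrame(rows, columns=["chrom", "pos"])
        df["id"] = df["chrom"] + ":" + df["pos"].astype(str)
        df["ref"] = "A"
        df["alt"] = "G"
        df["vtype"] = "SNP"
        return df


@dataclass(frozen=True)
class FounderPanel:
    """Per-breed allele frequencies plus the two planted causal loci.

    Convention: the ALT allele at ``causal_B`` is the melanin-enabling *B*
    allele, fixed in breed 0 (Liancheng-like) and absent from breed 1; the
    ALT allele at ``causal_R`` is *R*, fixed in breed 1 (Pekin-like) and
    absent from breed 0.  Both loci are fixed differences (delta-AF = 1) and
    must lie on different chromosomes, mirroring the *BBrr* x *bbRR* cross.
    """

    breed_names: tuple[str, str]
    allele_freqs: Mapping[str, Mapping[str, np.ndarray]]  # breed -> chrom -> freq
    causal_B: tuple[str, int]
    causal_R: tuple[str, int]

    def __post_init__(self) -> None:
        if self.causal_B[0] == self.causal_R[0]:
            raise ValueError("causal loci must lie on different chromosomes")
        for breed, per_chrom in self.allele_freqs.items():
            for chrom, f in per_chrom.items():
                f = np.asarray(f)
                if np.any((f < 0) | (f > 1)):
                    raise ValueError(f"allele frequencies outside [0,1] for {breed}/{chrom}")


@dataclass(frozen=True)
class CrossConfig:
    """Everything needed to reproduce a simulated cohort byte-for-byte."""

    layout: GenomeLayout
    founders: FounderPanel
    n_per_founder: tuple[int, int] = (59, 117)
    n_f1: int = 100
    n_f2: int = 400
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(*self.n_per_founder, self.n_f1, self.n_f2) < 0:
            raise ValueError("cohort counts must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulatedCohort:
    """A simulated panel: observed data plus the full generative truth."""

    dataset: VariantDataset          # genotypes with missingness applied
    metadata: pd.DataFrame           # sample_id, breed, generation, phenotype, sex
    haplotypes: np.ndarray           # (n_samples, 2, n_variants) truth, int8
    truth: dict                      # causal loci, diplotypes, crossovers

    @property
    def samples(self) -> list[str]:
        return self.dataset.samples


def default_layout(
    n_neutral_chroms: int = 6,
    neutral_length: int = 60_000_000,
    snp_density_per_mb: float = 14.0,
    base_rate: float = 1.0,
    min_morgans: float = 0.5,
    seed: int = 17,
) -> GenomeLayout:
    """A small multi-chromosome layout with the two causal chromosomes.

    Chromosomes are named after the biology being emulated: the *Bb* locus
    sits on "chr13" (the melanogenesis master-regulator region, 20 Mb) and
    the *Rr* locus on "chr33" (the melanosome-scaffold gene region, 10 Mb,
    around 5.3 Mb).  SNPs are placed at uniform density, so the two causal
    chromosomes carry only a few percent of all markers — as in a real
    genome, where no small chromosome's founder ancestry can dominate the
    relationship matrix or its principal components.

    Recombination follows an obligate-crossover map: each chromosome's
    genetic length is at least ``min_morgans`` (every bivalent gets a
    crossover per meiosis), which gives avian microchromosomes their
    characteristically high per-Mb rates.
    """
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", neutral_length) for i in range(n_neutral_chroms)]
    chroms += [("chr13", 20_000_000), ("chr33", 10_000_000)]
    positions, rates = {}, {}
    for name, length in chroms:
        n = int(round(length / 1e6 * snp_density_per_mb))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        positions[name] = pos.astype(np.int64)
        morgans = max(length / 1e6 * base_rate / 100.0, min_morgans)
        rates[name] = morgans * 100.0 / (length / 1e6)  # back to cM/Mb
    # Guarantee the causal positions exist as SNPs.
    positions["chr13"] = np.unique(np.append(positions["chr13"], 10_000_000))
    positions["chr33"] = np.unique(np.append(positions["chr33"], 5_303_994))
    return GenomeLayout(tuple(chroms), positions, rates)


CAUSAL_B_DEFAULT = ("chr13", 10_000_000)
CAUSAL_R_DEFAULT = ("chr33", 5_303_994)


def default_panel(
    layout: GenomeLayout,
    seed: int = 23,
    aim_fraction: float = 0.1,
    aim_freqs: tuple[float, float] = (0.02, 0.98),
    breed_names: tuple[str, str] = ("LC", "PK"),
    causal_B: tuple[str, int] = CAUSAL_B_DEFAULT,
    causal_R: tuple[str, int] = CAUSAL_R_DEFAULT,
) -> FounderPanel:
    """Draw founder allele frequencies for two strongly diverged breeds.

    Neutral SNP frequencies are drawn per breed from a symmetric Beta(0.8,
    0.8) truncated to [0.05, 0.95].  A fraction ``aim_fraction`` of SNPs are
    made ancestry-informative (``aim_freqs`` in one breed vs the other,
    0.02/0.98 by default, random orientation) so that delta-AF > 0.8 screens
    have genuine hits, as the fine-mapping stage requires; noise-free
    ancestry painting is obtained with ``aim_freqs=(0.0, 1.0)``.  Causal
    loci are always set to fixed differences.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, np.ndarray]] = {b: {} for b in breed_names}

    def _trunc_beta(size: int) -> np.ndarray:
        f = rng.beta(0.8, 0.8, size=size)
        return np.clip(f, 0.05, 0.95)

    for chrom, _ in layout.chromosomes:
        n = len(layout.snp_positions[chrom])
        f0, f1 = _trunc_beta(n), _trunc_beta(n)
        aim = rng.random(n) < aim_fraction
        orient = rng.random(n) < 0.5
        lo, hi = aim_freqs
        f0[aim] = np.where(orient[aim], lo, hi)
        f1[aim] = np.where(orient[aim], hi, lo)
        freqs[breed_names[0]][chrom] = f0
        freqs[breed_names[1]][chrom] = f1

    for (chrom, pos), lc_f, pk_f in ((causal_B, 1.0, 0.0), (causal_R, 0.0, 1.0)):
        idx = int(np.searchsorted(layout.snp_positions[chrom], pos))
        if idx >= len(layout.snp_positions[chrom]) or layout.snp_positions[chrom][idx] != pos:
            raise ValueError(f"causal position {chrom}:{pos} is not a SNP in the layout")
        freqs[breed_names[0]][chrom][idx] = lc_f
        freqs[breed_names[1]][chrom][idx] = pk_f
    return FounderPanel(breed_names, freqs, causal_B, causal_R)


def default_config(seed: int = 0, **overrides) -> CrossConfig:
    """Layout + panel + cohort sizes emulating the study panel, scaled down."""
    layout = default_layout(seed=seed + 1)
    panel = default_panel(layout, seed=seed + 2)
    return CrossConfig(layout=layout, founders=panel, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# simulation internals


def _causal_indices(config: CrossConfig) -> tuple[int, int]:
    slices = config.layout.chrom_slices()
    out = []
    for chrom, pos in (config.founders.causal_B, config.founders.causal_R):
        local = int(np.searchsorted(config.layout.snp_positions[chrom], pos))
        out.append(slices[chrom].start + local)
    return out[0], out[1]


def _flat_freqs(config: CrossConfig, breed: str) -> np.ndarray:
    per = config.founders.allele_freqs[breed]
    return np.concatenate([np.asarray(per[c]) for c, _ in config.layout.chromosomes])


def _draw_founder_haplotypes(config: CrossConfig, breed_idx: int, n: int, rng) -> np.ndarray:
    breed = config.founders.breed_names[breed_idx]
    freq = _flat_freqs(config, breed)
    if freq.size == 0:
        raise ValueError("layout has zero SNPs")
    haps = (rng.random((n, 2, freq.size)) < freq).astype(np.int8)
    b_idx, r_idx = _causal_indices(config)
    # Fixed alleles: breed 0 is BBrr (ALT at B, REF at R); breed 1 is bbRR.
    haps[:, :, b_idx] = 1 if breed_idx == 0 else 0
    haps[:, :, r_idx] = 0 if breed_idx == 0 else 1
    return haps


def make_gamete(
    parent_haplotypes: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One meiosis under the Haldane model.

    Per chromosome the crossover count is Poisson in the genetic length
    (length_bp / 1e6 * rate / 100 Morgans), breakpoints uniform in bp; the
    returned haplotype alternates parental origin at each breakpoint.
    Returns ``(haplotype, crossovers)`` with crossover bp positions recorded
    per chromosome.
    """
    if parent_haplotypes.shape[0] != 2:
        raise ValueError("parent diplotype must be a phased pair of haplotypes")
    m = parent_haplotypes.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    crossovers: dict[str, np.ndarray] = {}
    slices = layout.chrom_slices()
    for chrom, length in layout.chromosomes:
        sl = slices[chrom]
        morgans = length / 1e6 * layout.rate_of(chrom) / 100.0
        k = rng.poisson(morgans) if morgans > 0 else 0
        breaks = np.sort(rng.uniform(1, length, size=k)) if k else np.empty(0)
        start_phase = int(rng.integers(2))
        pos = layout.snp_positions[chrom]
        segment = np.searchsorted(breaks, pos)
        phase = (start_phase + segment) % 2
        gamete[sl] = parent_haplotypes[phase, np.arange(sl.start, sl.stop)]
        crossovers[chrom] = breaks
    return gamete, crossovers


def simulate_founders(config: CrossConfig) -> SimulatedCohort:
    """Founder-only cohort: genotypes binomial(2, freq) per breed."""
    return breed_cross(replace(config, n_f1=0, n_f2=0))


def _apply_missingness(genotypes: np.ndarray, rate: float, rng) -> np.ndarray:
    g = genotypes.copy()
    if rate > 0:
        g[rng.random(g.shape) < rate] = -1
    return g


def breed_cross(config: CrossConfig) -> SimulatedCohort:
    """Simulate founders, F1 and F2 with full truth records.

    F1 individuals each combine one gamete from a random breed-0 founder and
    one from a random breed-1 founder (hence all are *BbRr*, gray-feathered);
    F2 individuals combine two independent F1 gametes.
    """
    if config.n_f1 == 0 and config.n_f2 > 0:
        raise ValueError("cannot produce F2 individuals without F1 parents")
    rng = np.random.default_rng(config.seed)
    model = SegregationModel()
    b_idx, r_idx = _causal_indices(config)
    name0, name1 = config.founders.breed_names

    hap_blocks, meta_rows, crossover_log = [], [], {}
    for breed_idx, (breed, n) in enumerate(zip(config.founders.breed_names, config.n_per_founder)):
        haps = _draw_founder_haplotypes(config, breed_idx, n, rng)
        hap_blocks.append(haps)
        for i in range(n):
            meta_rows.append((f"{breed}{i + 1:03d}", breed, "F0", breed))

    founder_haps = np.concatenate(hap_blocks) if hap_blocks else np.empty((0, 2, config.layout.n_snps), np.int8)
    n0 = config.n_per_founder[0]

    f1_haps = np.empty((config.n_f1, 2, config.layout.n_snps), dtype=np.int8)
    for i in range(config.n_f1):
        mom = founder_haps[rng.integers(n0)] if n0 else None
        dad = founder_haps[n0 + rng.integers(config.n_per_founder[1])]
        if mom is None:
            raise ValueError("breed 0 has no founders to draw F1 parents from")
        sid = f"F1_{i + 1:03d}"
        g0, c0 = make_gamete(mom, config.layout, rng)
        g1, c1 = make_gamete(dad, config.layout, rng)
        f1_haps[i, 0], f1_haps[i, 1] = g0, g1
        crossover_log[sid] = {"maternal": c0, "paternal": c1}
        pheno = model.phenotype(int(g0[b_idx] + g1[b_idx]), int(g0[r_idx] + g1[r_idx]))
        meta_rows.append((sid, "F1", "F1", pheno))

    f2_haps = np.empty((config.n_f2, 2, config.layout.n_snps), dtype=np.int8)
    for i in range(config.n_f2):
        p0 = f1_haps[rng.integers(config.n_f1)]
        p1 = f1_haps[rng.integers(config.n_f1)]
        sid = f"F2_{i + 1:04d}"
        g0, c0 = make_gamete(p0, config.layout, rng)
        g1, c1 = make_gamete(p1, config.layout, rng)
        f2_haps[i, 0], f2_haps[i, 1] = g0, g1
        crossover_log[sid] = {"maternal": c0, "paternal": c1}
        pheno = model.phenotype(int(g0[b_idx] + g1[b_idx]), int(g0[r_idx] + g1[r_idx]))
        meta_rows.append((sid, "F2", "F2", pheno))

    haplotypes = np.concatenate([founder_haps, f1_haps, f2_haps])
    genotypes = haplotypes.sum(axis=1, dtype=np.int8)
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "breed", "generation", "phenotype"])
    metadata["sex"] = np.where(rng.random(len(metadata)) < 0.5, "F", "M")

    observed = _apply_missingness(genotypes, config.missing_rate, rng)
    variants = config.layout.variant_frame()
    dataset = VariantDataset(variants=variants, genotypes=observed, samples=list(metadata["sample_id"]))

    truth = {
        "causal_B": {"chrom": config.founders.causal_B[0], "pos": int(config.founders.causal_B[1]), "index": b_idx},
        "causal_R": {"chrom": config.founders.causal_R[0], "pos": int(config.founders.causal_R[1]), "index": r_idx},
        "causal_diplotypes": {
            sid: (int(genotypes[i, b_idx]), int(genotypes[i, r_idx]))
            for i, sid in enumerate(metadata["sample_id"])
        },
        "crossovers": crossover_log,
    }
    return SimulatedCohort(dataset=dataset, metadata=metadata, haplotypes=haplotypes, truth=truth)


# ---------------------------------------------------------------------------
# read-depth simulation


def simulate_depth(
    cohort: SimulatedCohort,
    planted_cnvs: Sequence[tuple[str, int, int, Mapping[str, float]]],
    window_bp: int = 1_000,
    mean_depth: float = 30.0,
    chroms: Sequence[str] | None = None,
    sample_depth_factor: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window Poisson read counts with planted copy-number variants.

    ``planted_cnvs`` entries are ``(chrom, start, end, {breed: copy_number})``
    with copy number on the diploid scale (2 = normal).  Window counts are
    Poisson(mean_depth * cn / 2 * sample_factor).  Returns ``(depth, truth)``
    where depth is a tidy frame (chrom, start, end, one column per sample)
    and truth holds the per-window per-sample planted copy number.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rng = np.random.default_rng(seed)
    layout_chroms = [c for c in dict(_cohort_layout_chroms(cohort)) if chroms is None or c in chroms]
    lengths = dict(_cohort_layout_chroms(cohort))
    for chrom, start, end, _ in planted_cnvs:
        if chrom not in lengths or start < 1 or end > lengths[chrom]:
            raise ValueError(f"planted CNV {chrom}:{start}-{end} outside the genome layout")

    samples = cohort.samples
    breeds = dict(zip(cohort.metadata["sample_id"], cohort.metadata["breed"]))
    factors = np.array([(sample_depth_factor or {}).get(s, 1.0) for s in samples])

    rows, cn_rows = [], []
    for chrom in layout_chroms:
        n_win = lengths[chrom] // window_bp
        starts = np.arange(n_win) * window_bp + 1
        ends = starts + window_bp - 1
        cn = np.full((n_win, len(samples)), 2.0)
        for c, s, e, per_breed in planted_cnvs:
            if c != chrom:
                continue
            hit = (starts <= e) & (ends >= s)
            for j, sid in enumerate(samples):
                if breeds[sid] in per_breed:
                    cn[hit, j] = per_breed[breeds[sid]]
        lam = mean_depth * cn / 2.0 * factors[None, :]
        counts = rng.poisson(lam)
        for w in range(n_win):
            rows.append((chrom, int(starts[w]), int(ends[w]), *counts[w]))
            cn_rows.append((chrom, int(starts[w]), int(ends[w]), *cn[w]))
    cols = ["chrom", "start", "end", *samples]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(cn_rows, columns=cols)


def _cohort_layout_chroms(cohort: SimulatedCohort) -> list[tuple[str, int]]:
    # Reconstruct chromosome extents from the variant table (upper bound on
    # length: last SNP position rounded up to the next Mb).
    out = []
    for chrom, grp in cohort.dataset.variants.groupby("chrom", sort=False):
        out.append((chrom, int(np.ceil(grp["pos"].max() / 1e6) * 1e6)))
    return out


# ---------------------------------------------------------------------------
# engineered candidate-region panel for the causative-variant screen


def simulate_screen_panel(
    n_decoys: int = 30,
    include_ld_twin: bool = True,
    n_indels: int = 2,
    region: tuple[str, int, int] = ("chr33", 5_240_000, 5_320_000),
    causal_pos: int = 5_303_994,
    group_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[VariantDataset, pd.DataFrame, dict]:
    """Synthetic candidate-region panel across seven duck groups.

    Builds genotypes for founder breeds (LC, PK), validation black-feathered
    breeds (MD, PT) and intercross phenotype groups (BF, GF, WB) in a single
    candidate region containing: one planted causal SNP whose genotype is
    perfectly concordant with the *Rr* phenotype in every group; optionally a
    second causal SNP in complete LD with it; decoy SNPs with high LC-vs-PK
    divergence but engineered failures in later screen steps; and planted
    causal-like indels (which the screen must exclude).  This is a synthetic
    stand-in for a multi-breed resequencing panel; it exists so the
    cross-breed screen can be exercised without real data.

    Returns ``(dataset, metadata, truth)`` with truth naming the causal
    variant ids.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(group_sizes or {"LC": 59, "PK": 117, "MD": 20, "PT": 3, "BF": 41, "GF": 67, "WB": 42})
    groups = [g for g, n in sizes.items() for _ in range(n)]
    samples = [f"{g}{i + 1:03d}" for g in sizes for i in range(sizes[g])]
    n = len(samples)
    group_arr = np.array(groups)

    # Count of the LC-associated (r) allele expected from each group's
    # R-locus genotype: rr -> 2, Rr -> 1, RR -> 0.
    r_dosage = {"LC": 2, "WB": 2, "GF": 1, "PK": 0, "MD": 0, "PT": 0, "BF": 0}

    chrom, lo, hi = region
    positions: list[int] = []
    columns: list[np.ndarray] = []
    vtypes: list[str] = []
    roles: list[str] = []

    def causal_column() -> np.ndarray:
        return np.array([r_dosage[g] for g in groups], dtype=np.int8)

    def add(pos: int, col: np.ndarray, vtype: str, role: str) -> None:
        positions.append(pos)
        columns.append(col.astype(np.int8))
        vtypes.append(vtype)
        roles.append(role)

    add(causal_pos, causal_column(), "SNP", "causal")
    if include_ld_twin:
        add(causal_pos + 3, causal_column(), "SNP", "causal")  # complete LD pair
    for i in range(n_indels):
        add(causal_pos + 10 + i, causal_column(), "indel", "indel_decoy")

    # Decoys cycle through three engineered failure modes.
    decoy_pos = np.sort(rng.choice(np.arange(lo, hi), size=n_decoys, replace=False))
    for i, pos in enumerate(decoy_pos):
        mode = i % 3
        col = np.zeros(n, dtype=np.int8)
        if mode == 0:
            # High LC-vs-PK divergence, but MD carries the LC allele: fails
            # the shared-divergence step (LC vs MD is undifferentiated).
            col[group_arr == "LC"] = 2
            col[group_arr == "MD"] = 2
            col[np.isin(group_arr, ["GF"])] = 1
        elif mode == 1:
            # Divergent and shared, but validation genotypes scrambled:
            # fails the strict genotype-phenotype concordance step.
            col = causal_column()
            md_idx = np.flatnonzero(group_arr == "MD")
            col[md_idx[: len(md_idx) // 2]] = 2
        else:
            # Moderate LC-vs-PK divergence only: fails the FST >= 0.8 step.
            col[group_arr == "LC"] = (rng.random(np.sum(group_arr == "LC")) < 0.6).astype(np.int8) * 2
            col[group_arr == "GF"] = 1
        # Shift any decoy colliding with an already-used position.
        while pos in positions:
            pos += 1
        add(int(pos), col, "SNP", f"decoy_mode{mode}")

    order = np.argsort(positions, kind="stable")
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.array(positions)[order],
            "id": [f"{chrom}:{positions[i]}" for i in order],
            "ref": ["A"] * len(order),
            "alt": ["AG" if vtypes[i] == "indel" else "G" for i in order],
            "vtype": [vtypes[i] for i in order],
        }
    )
    genotypes = np.stack([columns[i] for i in order], axis=1)
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "breed": groups,
            "generation": ["F0" if g in ("LC", "PK", "MD", "PT") else "F2" for g in groups],
            "phenotype": groups,
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        }
    )
    truth = {
        "causal_ids": [variants["id"].iloc[j] for j in range(len(order)) if roles[order[j]] == "causal"],
        "indel_ids": [variants["id"].iloc[j] for j in range(len(order)) if roles[order[j]] == "indel_decoy"],
        "region": region,
    }
    dataset = VariantDataset(variants=variants, genotypes=genotypes, samples=samples)
    return dataset, metadata, truth


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, metadata TSV and truth JSON for a simulated cohort."""
    from . import variant_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    variant_io.write_vcf(cohort.dataset, paths["vcf"])
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth = {
        "causal_B": cohort.truth["causal_B"],
        "causal_R": cohort.truth["causal_R"],
        "causal_diplotypes": cohort.truth["causal_diplotypes"],
        "crossovers": {
            sid: {par: {c: list(map(float, b)) for c, b in per.items()} for par, per in rec.items()}
            for sid, rec in cohort.truth["crossovers"].items()
        },
    }
    paths["truth"].write_text(json.dumps(truth))
    return paths
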