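"""Candidate-region fine-mapping by founder-ancestry painting.

In an F2 intercross every chromosome is a mosaic of the two founder breeds'
haplotypes.  At ancestry-informative SNPs (delta-AF > 0.8 between founders)
each individual's diplotype can be painted as homozygous-founder-1,
heterozygous, or homozygous-founder-2; positions where the painted state
switches are recombination breakpoints, reported as the uncertainty
interval between the two flanking informative SNPs (genotype data cannot
localize a crossover more finely).  Cutting the candidate region at the
union of the cohort's breakpoint intervals partitions it into haplotype
blocks; the block whose per-individual state is perfectly concordant with
the feather-melanin phenotype localizes the causal locus.

The module also implements the three-step cross-breed causative-variant
screen: (1) keep variants with founder-contrast FST >= 0.8, (2) keep
variants whose high divergence is shared across every white-founder vs
black-breed contrast (top-decile intersection), (3) keep variants whose
genotypes are completely concordant with phenotype in independent
validation breeds — with indels excluded up front, and complete-LD
survivors reported as one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import popgen
from .variant_io import MISSING, VariantDataset

__all__ = [
    "STATE_HOM_P2",
    "STATE_HET",
    "STATE_HOM_P1",
    "STATE_UNKNOWN",
    "CandidateRegion",
    "HaplotypeBlock",
    "ScreenReport",
    "informative_snps",
    "infer_ancestry",
    "find_breakpoints",
    "partition_blocks",
    "block_states",
    "block_concordance",
    "ld_r2",
    "causative_screen",
]

# Painted diplotype states, coded as the dosage of the founder-1-major
# allele: 2 copies -> homozygous founder 1, 1 -> heterozygous, 0 ->
# homozygous founder 2; -9 -> unknown (missing genotype).
STATE_HOM_P2: int = 0
STATE_HET: int = 1
STATE_HOM_P1: int = 2
STATE_UNKNOWN: int = -9


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int  # 1-based, inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class HaplotypeBlock:
    chrom: str
    start: int            # first member informative SNP position
    end: int              # last member informative SNP position
    snp_indices: np.ndarray  # indices into the informative-SNP axis


@dataclass
class ScreenReport:
    """Causative-screen outcome: per-variant step survival flags."""

    variants: pd.DataFrame       # id, chrom, pos, vtype, indel_excluded, step1..step3
    final_ids: list[str]
    ld_groups: list[list[str]] = field(default_factory=list)


def informative_snps(
    divergence: pd.DataFrame,
    region: CandidateRegion,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Founder-contrast variants in the region with delta-AF > threshold."""
    m = (
        (divergence["chrom"] == region.chrom)
        & (divergence["pos"] >= region.start)
        & (divergence["pos"] <= region.end)
        & (divergence["delta_af"] > threshold)
    )
    out = divergence.loc[m].sort_values("pos").reset_index(drop=True)
    if out.empty:
        import warnings

        warnings.warn("no ancestry-informative SNPs in the candidate region", stacklevel=2)
    return out


def infer_ancestry(
    dataset: VariantDataset,
    informative: pd.DataFrame,
    smooth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint founder ancestry at the informative SNPs.

    ``informative`` must carry chrom/pos and the founder-1 allele frequency
    column ``p1`` (from the founder divergence table): the founder-1-major
    allele is ALT where p1 > 0.5, REF otherwise.  Returns ``(positions,
    states)`` with states of shape (n_samples, n_informative).  With
    ``smooth`` a 3-SNP majority vote absorbs isolated genotyping noise
    (off by default).
    """
    if informative.empty:
        raise ValueError("no informative SNPs supplied")
    vt = dataset.variants
    key = vt["chrom"].astype(str) + ":" + vt["pos"].astype(str)
    col_of = {k: j for j, k in enumerate(key)}
    idx = []
    for _, row in informative.iterrows():
        k = f"{row['chrom']}:{row['pos']}"
        if k not in col_of:
            raise ValueError(f"informative SNP {k} not present in the dataset")
        idx.append(col_of[k])
    g = dataset.genotypes[:, idx]
    alt_is_p1 = (informative["p1"].to_numpy() > 0.5)
    states = np.where(alt_is_p1[None, :], g, 2 - g).astype(np.int8)
    states[g == MISSING] = STATE_UNKNOWN
    if smooth:
        states = _majority_smooth(states)
    positions = informative["pos"].to_numpy()
    return positions, states


def _majority_smooth(states: np.ndarray) -> np.ndarray:
    out = states.copy()
    n = states.shape[1]
    for j in range(1, n - 1):
        window = states[:, j - 1 : j + 2]
        for s in (STATE_HOM_P2, STATE_HET, STATE_HOM_P1):
            votes = (window == s).sum(axis=1)
            out[np.asarray(votes >= 2) & (states[:, j] != STATE_UNKNOWN), j] = s
    return out


def find_breakpoints(positions: np.ndarray, states: np.ndarray) -> list[tuple[int, int]]:
    """Breakpoint intervals of one individual's ancestry path.

    Unknown states are skipped (the last known state carries over); each
    change between consecutive known states yields one open interval
    ``(pos_left, pos_right)`` between the flanking informative SNPs.
    """
    known = np.flatnonzero(states != STATE_UNKNOWN)
    out = []
    for a, b in zip(known[:-1], known[1:]):
        if states[a] != states[b]:
            out.append((int(positions[a]), int(positions[b])))
    return out


def partition_blocks(
    breakpoints: Sequence[Sequence[tuple[int, int]]],
    positions: np.ndarray,
    region: CandidateRegion,
) -> list[HaplotypeBlock]:
    """Cut the region at the union of the cohort's breakpoint intervals.

    Blocks are maximal runs of informative SNPs not separated by any cut
    interval; k disjoint cut intervals yield k+1 blocks.  Informative SNPs
    falling strictly inside a (merged) cut interval are ancestry-ambiguous
    and belong to no block.
    """
    cuts = sorted({iv for per_ind in breakpoints for iv in per_ind})
    merged: list[list[int]] = []
    for lo, hi in cuts:
        if merged and lo < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    blocks: list[HaplotypeBlock] = []
    current: list[int] = []

    def flush() -> None:
        if current:
            blocks.append(
                HaplotypeBlock(
                    chrom=region.chrom,
                    start=int(positions[current[0]]),
                    end=int(positions[current[-1]]),
                    snp_indices=np.array(current),
                )
            )

    for i, pos in enumerate(positions):
        if any(lo < pos < hi for lo, hi in merged):
            continue  # inside a cut interval: ambiguous
        if current and any(positions[current[-1]] <= lo and hi <= pos for lo, hi in merged):
            flush()
            current = []
        current.append(i)
    flush()
    return blocks


def block_states(
    blocks: Sequence[HaplotypeBlock],
    states: np.ndarray,
    min_agreement: float = 0.8,
) -> np.ndarray:
    """Per-individual consensus state per block.

    The consensus requires >= ``min_agreement`` of the known member-SNP
    states to agree; otherwise (or with no known member states) the block
    state is unknown.
    """
    n = states.shape[0]
    out = np.full((n, len(blocks)), STATE_UNKNOWN, dtype=np.int8)
    for b, blk in enumerate(blocks):
        sub = states[:, blk.snp_indices]
        for s in (STATE_HOM_P2, STATE_HET, STATE_HOM_P1):
            known = (sub != STATE_UNKNOWN).sum(axis=1)
            votes = (sub == s).sum(axis=1)
            ok = (known > 0) & (votes >= min_agreement * known) & (votes > 0)
            out[ok, b] = s
    return out


#: Feather-melanin phenotype -> expected block state, founder-1 = the
#: white-feathered (rr) breed: WB is homozygous founder-1, GF heterozygous,
#: BF homozygous founder-2.
PHENOTYPE_STATE: dict[str, int] = {"WB": STATE_HOM_P1, "GF": STATE_HET, "BF": STATE_HOM_P2}


def block_concordance(
    blocks_state: np.ndarray,
    phenotypes: Sequence[str],
    expected: Mapping[str, int] = PHENOTYPE_STATE,
) -> np.ndarray:
    """Fraction of black-beaked individuals whose block state matches phenotype.

    Only individuals whose phenotype appears in ``expected`` (the *B_*
    black-beaked classes, where the feather-melanin locus is visible) are
    scored; unknown block states count as mismatches.  A block scoring 1.0
    is a candidate interval for the causal locus.
    """
    phen = np.asarray(phenotypes)
    mask = np.isin(phen, list(expected))
    if not mask.any():
        raise ValueError("no black-beaked individuals to score")
    want = np.array([expected[p] for p in phen[mask]])
    sub = blocks_state[mask]
    return (sub == want[:, None]).mean(axis=0)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD r^2: squared correlation of genotype dosages.

    Missing calls in either vector are dropped pairwise; returns NaN if
    either variant is monomorphic among the retained samples.
    """
    g1, g2 = np.asarray(g1), np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(float), g2[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _lc_allele_dosage(genotypes: np.ndarray, lc_idx: np.ndarray) -> np.ndarray:
    """Per-variant dosage matrix of the allele major in the white founder."""
    p_lc, _ = popgen.allele_freq(genotypes, lc_idx)
    alt_is_lc = p_lc > 0.5
    dos = np.where(alt_is_lc[None, :], genotypes, 2 - genotypes)
    dos[genotypes == MISSING] = MISSING
    return dos.astype(np.int8)


#: Expected dosage of the white-founder (r) allele by population/phenotype
#: label: rr carriers (white founder, WB) -> 2; heterozygotes (GF) -> 1;
#: RR carriers (black breeds, yellow-beak founder, BF) -> 0.
R_DOSAGE_BY_GROUP: dict[str, int] = {
    "LC": 2, "WB": 2, "GF": 1, "PK": 0, "BF": 0, "MD": 0, "PT": 0,
}


def causative_screen(
    dataset: VariantDataset,
    populations: Mapping[str, str] | pd.Series,
    region: CandidateRegion,
    founder_pops: tuple[str, str] = ("LC", "PK"),
    black_breeds: Sequence[str] = ("MD", "PT", "BF"),
    validation_pops: Sequence[str] = ("MD", "PT"),
    fst_min: float = 0.8,
    top_fraction: float = 0.1,
    group_dosage: Mapping[str, int] = R_DOSAGE_BY_GROUP,
    ld_group_r2: float = 0.999,
) -> ScreenReport:
    """Three-step cross-breed screen for causative variants in a region.

    Indels are excluded before step 1 and listed separately.  Step 1 keeps
    SNPs with founder-contrast FST >= ``fst_min``.  Step 2 keeps SNPs in the
    top ``top_fraction`` of FST in every white-founder vs black-breed
    contrast (shared high divergence).  Step 3 keeps SNPs whose genotype in
    every validation-breed individual equals the dosage implied by that
    breed's phenotype class (complete concordance, zero exceptions).
    Surviving SNPs in complete LD are reported as one group.  Empty
    survivors at any step yield an empty final set, not an error.
    """
    labels = pd.Series(dict(populations)) if not isinstance(populations, pd.Series) else populations
    vt = dataset.variants
    in_region = (
        (vt["chrom"] == region.chrom).to_numpy()
        & (vt["pos"] >= region.start).to_numpy()
        & (vt["pos"] <= region.end).to_numpy()
    )
    sub = dataset.take(in_region)
    svt = sub.variants
    ids = svt["id"].to_numpy() if "id" in svt else (svt["chrom"].astype(str) + ":" + svt["pos"].astype(str)).to_numpy()

    is_indel = (svt["vtype"] == "indel").to_numpy()
    step1 = np.zeros(len(svt), dtype=bool)
    step2 = np.zeros(len(svt), dtype=bool)
    step3 = np.zeros(len(svt), dtype=bool)

    def _contrast_fst(p_a: str, p_b: str) -> np.ndarray:
        div = popgen.divergence_table(sub, labels, p_a, p_b)
        keyed = dict(zip(div["chrom"].astype(str) + ":" + div["pos"].astype(str), div["fst"]))
        key = svt["chrom"].astype(str) + ":" + svt["pos"].astype(str)
        return np.array([keyed.get(k, np.nan) for k in key])

    lc, pk = founder_pops
    fst_founder = _contrast_fst(lc, pk)
    step1 = ~is_indel & (np.nan_to_num(fst_founder, nan=-1.0) >= fst_min)

    if step1.any():
        shared = step1.copy()
        for breed in black_breeds:
            f = _contrast_fst(lc, breed)
            vals = f[step1]
            thresh = np.nanquantile(vals, 1 - top_fraction) if np.isfinite(vals).any() else np.inf
            shared &= np.nan_to_num(f, nan=-np.inf) >= thresh
        step2 = shared

    if step2.any():
        lc_idx = np.array([i for i, s in enumerate(sub.samples) if labels.get(s) == lc])
        dosage = _lc_allele_dosage(sub.genotypes, lc_idx)
        val_rows = [
            (i, group_dosage[labels[s]])
            for i, s in enumerate(sub.samples)
            if labels.get(s) in validation_pops and labels[s] in group_dosage
        ]
        if not val_rows:
            raise ValueError("validation populations are empty")
        rows = np.array([r for r, _ in val_rows])
        want = np.array([w for _, w in val_rows])
        g = dosage[rows]
        concordant = ((g == want[:, None]) | (g == MISSING)).all(axis=0)
        step3 = step2 & concordant

    final = list(ids[step3])
    groups: list[list[str]] = []
    if final:
        fin_idx = np.flatnonzero(step3)
        assigned: set[int] = set()
        for a in fin_idx:
            if a in assigned:
                continue
            grp = [a]
            assigned.add(a)
            for b in fin_idx:
                if b in assigned:
                    continue
                r2 = ld_r2(sub.genotypes[:, a], sub.genotypes[:, b])
                if r2 >= ld_group_r2:
                    grp.append(b)
                    assigned.add(b)
            groups.append([ids[j] for j in grp])

    report_df = pd.DataFrame(
        {
            "id": ids,
            "chrom": svt["chrom"].to_numpy(),
            "pos": svt["pos"].to_numpy(),
            "vtype": svt["vtype"].to_numpy(),
            "indel_excluded": is_indel,
            "step1": step1,
            "step2": step2,
            "step3": step3,
        }
    )
    return ScreenReport(variants=report_df, final_ids=final, ld_groups=groups)
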