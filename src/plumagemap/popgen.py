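"""Between-population divergence: allele frequencies, delta-AF and FST.

Per-SNP FST uses the Hudson estimator (robust to unequal sample sizes in a
two-population contrast); window averages use the Bhatia ratio-of-averages
(sum of numerators over sum of denominators within each window) rather than
an average of ratios, which would be dominated by low-information SNPs.
Windows are tiled half-open in fixed steps from coordinate 1.  A
Weir-Cockerham per-SNP estimator is available behind a flag.

Negative per-SNP estimates (finite-sample noise around zero differentiation)
are kept as computed in the table and in window sums.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, VariantDataset

__all__ = [
    "allele_freq",
    "delta_af",
    "fst_hudson",
    "fst_weir_cockerham",
    "divergence_table",
    "window_fst",
]


def allele_freq(genotypes: np.ndarray, sample_idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and non-missing allele count per variant.

    ``sample_idx`` selects the population's rows of the genotype matrix.
    Variants where every call is missing get frequency NaN and n = 0.
    """
    idx = np.asarray(sample_idx)
    if idx.size == 0:
        raise ValueError("population is empty")
    g = genotypes[idx]
    present = g != MISSING
    n = 2 * present.sum(axis=0)
    alt = np.where(present, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return p, n


def delta_af(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Absolute allele-frequency difference |p1 - p2|."""
    return np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))


def fst_hudson(p1, n1, p2, n2, return_parts: bool = False):
    """Hudson's two-population FST estimator, per SNP.

    numerator   = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    ``n1``/``n2`` are allele counts (2x individuals) and must be >= 2.  The
    estimate is undefined (NaN) where both populations are fixed for the
    same allele (denominator 0).  ``return_parts`` also yields numerator and
    denominator for ratio-of-averages windowing.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("allele counts must be >= 2 in both populations")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    if return_parts:
        return fst, num, den
    return fst


def fst_weir_cockerham(p1, n1, p2, n2) -> np.ndarray:
    """Weir-Cockerham theta for two populations from allele frequencies.

    Haploid-count form (no within-individual heterozygosity correction),
    adequate for the allele-frequency tables this module produces.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float) / 2.0, np.asarray(n2, float) / 2.0  # individuals
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b > 0, a / (a + b), np.nan)
    return theta


def divergence_table(
    dataset: VariantDataset,
    populations: pd.Series | dict,
    pop1: str,
    pop2: str,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-variant divergence between two labelled populations.

    ``populations`` maps sample_id -> label.  Returns chrom, pos, p1, p2,
    n1, n2, delta_af, fst (plus fst_num/fst_den for windowing).  Variants
    with an undefined frequency in either population are dropped.
    """
    labels = pd.Series(populations)
    idx1 = [i for i, s in enumerate(dataset.samples) if labels.get(s) == pop1]
    idx2 = [i for i, s in enumerate(dataset.samples) if labels.get(s) == pop2]
    p1, n1 = allele_freq(dataset.genotypes, idx1)
    p2, n2 = allele_freq(dataset.genotypes, idx2)
    ok = ~(np.isnan(p1) | np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    if estimator == "hudson":
        fst, num, den = fst_hudson(p1[ok], n1[ok], p2[ok], n2[ok], return_parts=True)
    elif estimator == "weir-cockerham":
        fst = fst_weir_cockerham(p1[ok], n1[ok], p2[ok], n2[ok])
        num, den = fst, np.ones_like(fst)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    vt = dataset.variants.loc[ok].reset_index(drop=True)
    return pd.DataFrame(
        {
            "chrom": vt["chrom"],
            "pos": vt["pos"],
            "id": vt.get("id", vt["chrom"].astype(str) + ":" + vt["pos"].astype(str)),
            "p1": p1[ok],
            "p2": p2[ok],
            "n1": n1[ok],
            "n2": n2[ok],
            "delta_af": delta_af(p1[ok], p2[ok]),
            "fst": fst,
            "fst_num": num,
            "fst_den": den,
        }
    )


def window_fst(divergence: pd.DataFrame, window_bp: int = 10_000) -> pd.DataFrame:
    """Ratio-of-averages FST in fixed windows tiled from coordinate 1.

    Windows are half-open ``[start, start + window_bp)`` and only windows
    holding at least one SNP are emitted; each window's value is the sum of
    Hudson numerators over the sum of denominators across its member SNPs.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = divergence.copy()
    df["window_start"] = ((df["pos"] - 1) // window_bp) * window_bp + 1
    rows = []
    for (chrom, start), grp in df.groupby(["chrom", "window_start"], sort=True):
        den = grp["fst_den"].sum()
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(start + window_bp - 1),
                "mean_fst": grp["fst_num"].sum() / den if den > 0 else np.nan,
                "n_snps": len(grp),
            }
        )
    return pd.DataFrame(rows)
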