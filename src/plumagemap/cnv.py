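"""Windowed read-depth copy-number genotyping.

Raw per-window read counts (fixed 1,000-bp windows) are library-size
normalized, then expressed as a ratio to the median depth of a reference
population (the yellow-beaked founder breed) in the same window.  On the
resulting diploid-relative scale the copy-number classes are:

    ratio 1   -> normal diploidy
    ratio 0.5 -> loss of heterozygosity (one copy)
    ratio 0   -> homozygous loss
    ratio 1.5 -> heterozygous duplication (three copies)
    ratio 2   -> homozygous duplication (four copies)
    ratio above 2.25 -> complex duplication

Class boundaries sit at the midpoints between adjacent class values
(0.25, 0.75, 1.25, 1.75, 2.25), with exact boundary values rounding up.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CN_CLASSES", "COMPLEX", "normalize_depth", "classify_cn", "call_cnvs"]

CN_CLASSES: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
_BOUNDARIES = np.array([0.25, 0.75, 1.25, 1.75])
COMPLEX: float = np.inf  # sentinel class for ratios beyond 2.25


def normalize_depth(
    depth: pd.DataFrame,
    samples: Sequence[str],
    reference_samples: Sequence[str],
) -> pd.DataFrame:
    """Depth ratios relative to a reference population, per window.

    ``depth`` holds chrom/start/end plus one raw-count column per sample.
    Each sample's counts are first scaled so all libraries have the mean
    total count (global coverage differences cancel), then divided by the
    per-window median of the scaled reference samples.  Windows whose
    reference median is zero are masked (NaN).  Returns the same frame
    shape with ratio columns, plus ``log2_fc`` companions.
    """
    if len(reference_samples) == 0:
        raise ValueError("reference group is empty")
    counts = depth[list(samples)].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    scaled = counts * (totals.mean() / totals)[None, :]
    ref_cols = [list(samples).index(s) for s in reference_samples]
    ref_median = np.median(scaled[:, ref_cols], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ref_median[:, None] > 0, scaled / ref_median[:, None], np.nan)
        log2fc = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), -np.inf)
        log2fc = np.where(np.isnan(ratio), np.nan, log2fc)
    cols = {s: ratio[:, j] for j, s in enumerate(samples)}
    cols.update({f"{s}_log2fc": log2fc[:, j] for j, s in enumerate(samples)})
    return pd.concat([depth[["chrom", "start", "end"]].reset_index(drop=True), pd.DataFrame(cols)], axis=1)


def classify_cn(ratio) -> np.ndarray | float:
    """Map a depth ratio to its copy-number class.

    Nearest of {0, 0.5, 1, 1.5, 2} with ties rounding up; ratios above 2.25
    are complex duplications (returned as ``inf``); NaN propagates.
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("depth ratios must be non-negative")
    idx = np.searchsorted(_BOUNDARIES, arr, side="right")
    classes = np.array(CN_CLASSES)[np.clip(idx, 0, len(CN_CLASSES) - 1)]
    out = np.where(arr > 2.25, COMPLEX, classes)
    out = np.where(np.isnan(arr), np.nan, out)
    return out if np.ndim(ratio) else float(out)


def call_cnvs(
    depth: pd.DataFrame,
    samples: Sequence[str],
    reference_samples: Sequence[str],
) -> pd.DataFrame:
    """Normalize and classify in one pass: tidy per-window per-sample calls."""
    ratios = normalize_depth(depth, samples, reference_samples)
    rows = []
    for s in samples:
        r = ratios[s].to_numpy()
        cls = classify_cn(np.nan_to_num(r, nan=1.0))
        cls = np.where(np.isnan(r), np.nan, cls)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": ratios["chrom"],
                    "start": ratios["start"],
                    "end": ratios["end"],
                    "sample": s,
                    "depth_ratio": r,
                    "log2_fc": ratios[f"{s}_log2fc"],
                    "cn_class": cls,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
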