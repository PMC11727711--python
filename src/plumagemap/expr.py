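"""Expression quantification utilities: CPM, group log2 fold change, 2^-ddCt.

Covers the bulk-expression and qPCR arithmetic used when nominating a
candidate gene by differential expression between black- and
white-feathered birds: counts-per-million normalization of read counts,
log2 fold change between sample groups with a pseudocount, and relative
qPCR quantification against a reference gene and calibrator condition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["cpm", "group_log2fc", "ddct_fold"]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / library_size`` per sample column.

    Library size is the column sum; a zero library is an error.  Column
    sums of the result are 1e6 for every sample.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")
    return counts * 1e6 / lib


def group_log2fc(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_a + c) / (mean_b + c)) between sample groups."""
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    mean_a = expr[list(group_a)].mean(axis=1)
    mean_b = expr[list(group_b)].mean(axis=1)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def ddct_fold(
    ct_target: float | Sequence[float],
    ct_reference: float | Sequence[float],
    ct_target_calibrator: float | Sequence[float],
    ct_reference_calibrator: float | Sequence[float],
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt_sample = Ct(target) - Ct(reference gene); ddCt subtracts the
    calibrator condition's dCt; the result is 2^-ddCt.  Sequences are
    treated as technical replicates and averaged before dCt.
    """
    t = float(np.mean(ct_target))
    r = float(np.mean(ct_reference))
    tc = float(np.mean(ct_target_calibrator))
    rc = float(np.mean(ct_reference_calibrator))
    ddct = (t - r) - (tc - rc)
    return float(2.0 ** (-ddct))
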