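"""Two-locus segregation model for duck plumage colour, with epistasis.

Plumage in the Liancheng x Pekin intercross is controlled by two unlinked
autosomal loci.  The *Bb* locus gates melanin synthesis: *B_* birds can make
melanin (black beak), while *bb* birds cannot and are white-feathered with a
yellow beak regardless of the second locus (recessive epistasis).  On a *B_*
background the *Rr* locus acts with incomplete dominance on feather melanin:
*RR* -> black feathers (BF), *Rr* -> gray feathers (GF), *rr* -> white
feathers with a black beak (WB).  A BbRr x BbRr intercross therefore
segregates the four classes BF:GF:WB:WY at 3:6:3:4.

This module enumerates those class probabilities exactly, produces expected
counts, and runs the Pearson chi-square goodness-of-fit test against a
specified ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "PHENOTYPE_CLASSES",
    "SegregationModel",
    "GofResult",
    "default_phenotype_map",
    "enumerate_f2_ratio",
    "expected_counts",
    "chisq_gof",
    "observed_ratio",
]

#: Phenotype classes in canonical order: black-feathered/black-beaked,
#: gray-feathered/black-beaked, white-feathered/black-beaked,
#: white-feathered/yellow-beaked.
PHENOTYPE_CLASSES: tuple[str, ...] = ("BF", "GF", "WB", "WY")


def default_phenotype_map(n_b: int, n_r: int) -> str:
    """Map a causal diplotype to a phenotype class.

    Parameters are allele dosages: ``n_b`` copies of the dominant
    melanin-enabling *B* allele and ``n_r`` copies of the incompletely
    dominant feather-melanin *R* allele, each in {0, 1, 2}.
    """
    if n_b == 0:  # bb is epistatic: no melanin anywhere -> white/yellow beak
        return "WY"
    return {2: "BF", 1: "GF", 0: "WB"}[n_r]


@dataclass(frozen=True)
class SegregationModel:
    """Genotype->phenotype map for the two-locus plumage model."""

    locus_names: tuple[str, str] = ("Bb", "Rr")
    phenotype_map: Callable[[int, int], str] = default_phenotype_map
    classes: tuple[str, ...] = PHENOTYPE_CLASSES

    def phenotype(self, n_b: int, n_r: int) -> str:
        cls = self.phenotype_map(n_b, n_r)
        if cls not in self.classes:
            raise ValueError(
                f"phenotype map returned {cls!r}, not one of {self.classes}"
            )
        return cls


@dataclass(frozen=True)
class GofResult:
    """Pearson goodness-of-fit result against an a-priori class ratio."""

    chi2: float
    df: int
    p: float
    expected: dict[str, float]


def _dosage_probs() -> dict[int, Fraction]:
    # Offspring allele dosage from a het x het cross: 1/4, 1/2, 1/4.
    return {0: Fraction(1, 4), 1: Fraction(1, 2), 2: Fraction(1, 4)}


def enumerate_f2_ratio(model: SegregationModel | None = None) -> dict[str, Fraction]:
    """Exact F2 phenotype-class probabilities of a BbRr x BbRr intercross.

    Enumerates the 16 equiprobable two-gamete combinations (equivalently the
    9 diplotypes with their binomial weights) and accumulates the exact
    rational probability of each phenotype class.  The default model gives
    BF:GF:WB:WY = 3:6:3:4 over 16.
    """
    if model is None:
        model = SegregationModel()
    probs: dict[str, Fraction] = {c: Fraction(0) for c in model.classes}
    dosage = _dosage_probs()
    for n_b, p_b in dosage.items():
        for n_r, p_r in dosage.items():
            cls = model.phenotype(n_b, n_r)
            probs[cls] += p_b * p_r
    assert sum(probs.values()) == 1
    return probs


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_counts(
    n: int, ratio: Mapping[str, Fraction | float]
) -> tuple[dict[str, float], dict[str, int]]:
    """Expected class counts ``E_k = n * p_k``, real-valued and integer views.

    The integer view rounds half-away-from-zero, then repairs the class with
    the largest fractional remainder (or trims the smallest) so the integers
    sum exactly to ``n``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    total = sum(Fraction(p) if isinstance(p, Fraction) else p for p in ratio.values())
    if abs(float(total) - 1.0) > 1e-9:
        raise ValueError(f"class probabilities sum to {float(total)}, not 1")
    real = {k: float(n * Fraction(p) if isinstance(p, Fraction) else n * p) for k, p in ratio.items()}
    ints = {k: _round_half_away(v) for k, v in real.items()}
    deficit = n - sum(ints.values())
    # Repair: hand surplus to the largest remainders, take from the smallest.
    remainders = sorted(real, key=lambda k: real[k] - math.floor(real[k]), reverse=deficit > 0)
    i = 0
    step = 1 if deficit > 0 else -1
    while deficit != 0:
        ints[remainders[i % len(remainders)]] += step
        deficit -= step
        i += 1
    return real, ints


def chisq_gof(
    observed: Mapping[str, int], ratio: Mapping[str, Fraction | float]
) -> GofResult:
    """Pearson chi-square goodness of fit of observed class counts to a ratio.

    Expected counts are the real-valued ``n * p_k`` (never the rounded
    integers); df = k - 1 since the ratio is specified a priori.
    """
    classes = list(observed)
    if set(classes) != set(ratio):
        raise ValueError("observed and ratio must cover the same classes")
    n = sum(observed.values())
    real, _ = expected_counts(n, ratio)
    if any(e <= 0 for e in real.values()):
        raise ValueError("all expected counts must be positive")
    chi2 = sum((observed[k] - real[k]) ** 2 / real[k] for k in classes)
    df = len(classes) - 1
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(chi2=float(chi2), df=df, p=p, expected=real)


def observed_ratio(
    observed: Mapping[str, int],
    anchor_class: str,
    anchor_value: float = 3,
    decimals: int = 1,
) -> dict[str, float]:
    """Report observed counts as a ratio anchored at one class.

    Each class is ``O_k * anchor_value / O_anchor`` rounded
    half-away-from-zero to ``decimals`` places (e.g. 235:452:234:360
    anchored at BF=3 -> 3 : 5.8 : 3 : 4.6).
    """
    if observed.get(anchor_class, 0) <= 0:
        raise ValueError("anchor class count must be positive")
    scale = 10**decimals
    out = {}
    for k, o in observed.items():
        v = o * anchor_value / observed[anchor_class]
        out[k] = _round_half_away(v * scale) / scale
    return out
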