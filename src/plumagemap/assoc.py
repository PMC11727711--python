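"""Mixed-linear-model association scan (EMMAX-style).

The model is ``y = Xb + g + e`` with a polygenic random effect whose
covariance is proportional to a genomic relationship matrix G:
``g ~ N(0, sigma_g^2 G)``, ``e ~ N(0, sigma_e^2 I)``.  Variance components
are estimated once on the null model by profiled REML over
``delta = sigma_e^2 / sigma_g^2`` (a single eigendecomposition of G makes
the profile cheap to evaluate), then held fixed while every variant is
tested by generalized least squares on eigen-rotated ("whitened") data —
the approximation popularized by the EMMAX program.

Fixed effects are an intercept, a sex indicator, the top principal
components of G (3 by default, to absorb founder-breed stratification in an
intercross panel), and optionally the genotype of a conditioning variant for
re-scans after peeling off a known signal.

Phenotype coding: plumage classes are scored as an ordinal melanin dose,
WY=0 < WB=1 < GF=2 < BF=3 (both loci move the score monotonically); a
restricted coding over black-beaked birds only (WB=0, GF=1, BF=2) is
available for fine-scans of the feather-melanin locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variant_io import MISSING, VariantDataset

__all__ = [
    "ORDINAL_CODING",
    "BLACK_BEAK_CODING",
    "LMMFit",
    "encode_phenotype",
    "grm",
    "pca_covariates",
    "build_covariates",
    "fit_null_lmm",
    "scan",
    "conditional_scan",
    "bonferroni_threshold",
]

ORDINAL_CODING: dict[str, float] = {"WY": 0.0, "WB": 1.0, "GF": 2.0, "BF": 3.0}
BLACK_BEAK_CODING: dict[str, float] = {"WB": 0.0, "GF": 1.0, "BF": 2.0}

P_FLOOR = 1e-300  # keeps -log10(p) finite


def encode_phenotype(classes: Sequence[str], coding: Mapping[str, float] = ORDINAL_CODING) -> np.ndarray:
    """Numeric phenotype vector from class labels; unmapped labels -> NaN."""
    return np.array([coding.get(c, np.nan) for c in classes], dtype=float)


def _impute_standardize(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls, centre by 2p and scale by sqrt(2p(1-p)).

    Returns (Z, polymorphic_mask); monomorphic variants get zero columns.
    """
    g = genotypes.astype(float)
    miss = genotypes == MISSING
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    inds = np.where(miss)
    g[inds] = mean[inds[1]]
    p = mean / 2.0
    var = 2.0 * p * (1.0 - p)
    poly = (var > 0) & (np.std(g, axis=0) > 0)
    Z = np.zeros_like(g)
    Z[:, poly] = (g[:, poly] - 2.0 * p[poly]) / np.sqrt(var[poly])
    return Z, poly


def grm(genotypes: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix ``ZZ'/m`` from standardized genotypes.

    Missing calls are mean-imputed per variant; monomorphic variants are
    skipped (they carry no relationship information).
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least two samples")
    Z, poly = _impute_standardize(genotypes)
    m = int(poly.sum())
    if m == 0:
        raise ValueError("all variants are monomorphic")
    return Z[:, poly] @ Z[:, poly].T / m


def pca_covariates(G: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal-component scores of the relationship matrix.

    Scores are eigenvectors scaled by sqrt(eigenvalue), with a deterministic
    sign convention: the largest-magnitude loading of each component is
    positive.
    """
    n = G.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if k == 0:
        return np.empty((n, 0))
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1][:k]
    scores = U[:, order] * np.sqrt(np.maximum(lam[order], 0))
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def build_covariates(
    n: int,
    sex: Sequence[str] | None = None,
    pcs: np.ndarray | None = None,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the fixed-effect matrix: intercept [, sex indicator][, PCs][, extra]."""
    cols = [np.ones((n, 1))]
    if sex is not None:
        cols.append((np.asarray(sex) == "M").astype(float).reshape(-1, 1))
    if pcs is not None and pcs.size:
        cols.append(np.asarray(pcs, dtype=float))
    if extra is not None and np.asarray(extra).size:
        cols.append(np.asarray(extra, dtype=float).reshape(n, -1))
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return X


@dataclass
class LMMFit:
    """Null-model REML fit: variance components and the cached eigensystem."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    degenerate: bool = False

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


def _reml_profile(delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> tuple[float, float]:
    """Profiled REML log-likelihood at delta and the implied sigma_g^2."""
    n, p = Xt.shape
    d = lam + delta
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XX = Xt.T @ XtW
    beta = np.linalg.solve(XX, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r * w))
    df = n - p
    sigma_g2 = max(rss / df, 1e-300)  # guard the log for constant phenotypes
    sign, logdet_XX = np.linalg.slogdet(XX)
    # REML likelihood of the transformed model, up to a constant in the data.
    ll = -0.5 * (df * (np.log(2 * np.pi * sigma_g2) + 1) + np.sum(np.log(d)) + logdet_XX)
    return ll, sigma_g2


def fit_null_lmm(y: np.ndarray, X: np.ndarray, G: np.ndarray) -> LMMFit:
    """REML variance components by 1-D search over log10(delta) in [-5, 5].

    A 100-point grid locates the optimum; a bracketed golden-section /
    Brent refinement polishes it.  With G = I the profile is flat in delta
    (any split of the OLS residual variance fits equally well); the grid
    optimum is returned and the fit flagged degenerate when y carries no
    variance after covariate adjustment.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n or G.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and G")
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values; mask samples first")
    lam, U = np.linalg.eigh(G)
    if lam.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    lam = np.maximum(lam, 0.0)
    yt, Xt = U.T @ y, U.T @ X

    grid = np.logspace(-5, 5, 100)
    lls = np.array([_reml_profile(d, lam, yt, Xt)[0] for d in grid])
    i = int(np.argmax(lls))

    def neg(ld: float) -> float:
        return -_reml_profile(10.0**ld, lam, yt, Xt)[0]

    lo = np.log10(grid[max(i - 1, 0)])
    hi = np.log10(grid[min(i + 1, len(grid) - 1)])
    mid = np.log10(grid[i])
    try:
        if lo < mid < hi and neg(mid) < min(neg(lo), neg(hi)):
            res = optimize.minimize_scalar(neg, bracket=(lo, mid, hi), method="golden")
        else:
            res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded")
        best = float(res.x)
    except Exception:
        best = mid
    delta = 10.0**best
    ll, sigma_g2 = _reml_profile(delta, lam, yt, Xt)
    sigma_e2 = delta * sigma_g2
    degenerate = sigma_g2 + sigma_e2 < 1e-12
    return LMMFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=ll,
        eigvals=lam,
        eigvecs=U,
        degenerate=degenerate,
    )


def _whiten(fit: LMMFit, arr: np.ndarray) -> np.ndarray:
    w = 1.0 / np.sqrt(fit.eigvals + fit.delta)
    return (fit.eigvecs.T @ arr) * (w[:, None] if arr.ndim == 2 else w)


def scan(
    dataset: VariantDataset,
    y: np.ndarray,
    X: np.ndarray,
    fit: LMMFit,
) -> pd.DataFrame:
    """Per-variant GLS Wald tests with variance components fixed at the null.

    Each variant's genotype (mean-imputed) is tested on the whitened data;
    the Wald statistic beta^2/se^2 is referred to chi-square(1).  Variants
    collinear with the covariates (including monomorphic ones) get NaN
    effect and p.  Returns a frame with CHR, POS, REF, ALT, BETA, SE, STAT,
    P and NEG_LOG10_P.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    g = dataset.genotypes.astype(float)
    miss = dataset.genotypes == MISSING
    if miss.any():
        gm = g.copy()
        gm[miss] = np.nan
        mean = np.nanmean(gm, axis=0)
        mean = np.nan_to_num(mean)
        idx = np.where(miss)
        g[idx] = mean[idx[1]]

    yw = _whiten(fit, y)
    Xw = _whiten(fit, X)
    Gw = _whiten(fit, g)
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gr = Gw - Q @ (Q.T @ Gw)

    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    yy = float(yr @ yr)
    dof = n - X.shape[1] - 1
    ok = gg > 1e-10 * max(n, 1)
    beta = np.full(gg.shape, np.nan)
    se = np.full(gg.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = gy[ok] / gg[ok]
        rss = np.maximum(yy - beta[ok] * gy[ok], 0.0)
        sigma2 = rss / dof
        se[ok] = np.sqrt(sigma2 / gg[ok])
    stat = (beta / se) ** 2
    p = stats.chi2.sf(stat, 1)
    p = np.where(np.isnan(stat), np.nan, np.maximum(p, P_FLOOR))
    vt = dataset.variants
    return pd.DataFrame(
        {
            "CHR": vt["chrom"].to_numpy(),
            "POS": vt["pos"].to_numpy(),
            "REF": vt["ref"].to_numpy(),
            "ALT": vt["alt"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "STAT": stat,
            "P": p,
            "NEG_LOG10_P": -np.log10(p),
        }
    )


def conditional_scan(
    dataset: VariantDataset,
    y: np.ndarray,
    X: np.ndarray,
    fit: LMMFit,
    condition_on: tuple[str, int],
) -> pd.DataFrame:
    """Re-scan with a conditioning variant's genotype as an extra covariate.

    The conditioning variant itself is reported with NaN statistics.  Used
    to peel off a dominant signal (e.g. the epistatic melanin-gate locus)
    and expose secondary loci, mirroring a chr13 -> chr33 style re-scan.
    """
    chrom, pos = condition_on
    vt = dataset.variants
    hit = np.flatnonzero((vt["chrom"] == chrom).to_numpy() & (vt["pos"] == pos).to_numpy())
    if hit.size == 0:
        raise ValueError(f"conditioning variant {chrom}:{pos} not found")
    j = int(hit[0])
    gcol = dataset.genotypes[:, j].astype(float)
    gcol[dataset.genotypes[:, j] == MISSING] = np.nan
    if np.nanstd(gcol) == 0:
        raise ValueError("conditioning variant is monomorphic")
    gcol = np.where(np.isnan(gcol), np.nanmean(gcol), gcol)
    X_aug = np.hstack([X, gcol.reshape(-1, 1)])
    out = scan(dataset, y, X_aug, fit)
    out.loc[j, ["BETA", "SE", "STAT", "P", "NEG_LOG10_P"]] = np.nan
    return out


def bonferroni_threshold(alpha: float = 0.01, n_snps: int = 1) -> float:
    """Genome-wide significance on the -log10(p) scale: -log10(alpha / N)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return float(-np.log10(alpha / n_snps))
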