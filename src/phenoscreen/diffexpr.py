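"""Self-contained negative-binomial differential expression.

A deliberately compact two-group pipeline in the median-of-ratios /
NB-Wald tradition:

1. ``size_factors`` — per-sample median-of-ratios normalization.
2. ``estimate_dispersion`` — per-gene method-of-moments dispersion on
   normalized counts pooled within groups, shrunk toward a mean-dispersion
   trend (lowess on the log scale).
3. ``nb_wald_test`` — per-gene NB GLM with log link, design
   intercept + group indicator and log size factors as offsets, fitted by
   iteratively reweighted least squares; Wald statistic log2fc/se against a
   standard normal; BH adjustment over the tested genes.
4. ``call_degs`` — FDR threshold split into up/down sets.

The NB is parameterized by mean m and dispersion alpha with variance
m + alpha*m**2; alpha = 0 is Poisson.  Compared with full DESeq2 there is no
outlier handling, no independent filtering and no fold-change shrinkage; a
small ridge on the group coefficient keeps all-zero-in-one-group genes
finite.  Genes with zero counts in every sample are flagged untested (NaN
statistics) and excluded from the BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .correlation import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "call_degs",
    "DEResult",
]

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over reference genes of count_gj / geometric-mean_g.
    Reference genes are those with nonzero counts in all samples; if none
    exist, rerun with ``pseudo_reference=True`` to take geometric means over
    nonzero entries only.
    """
    mat = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(mat > 0, np.log(mat), np.nan)
        n_pos = (~np.isnan(logc)).sum(axis=1)
        usable = n_pos > 0
        geo = np.exp(np.nanmean(logc[usable], axis=1))
        ratios = np.where(mat[usable] > 0, mat[usable] / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        all_pos = (mat > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True")
        ref = mat[all_pos]
        geo = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
    if not (factors > 0).all():
        raise ValueError("non-positive size factor; library too sparse")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    factors: pd.Series | None = None,
    trend_weight: float = 0.75,
    lowess_frac: float = 0.4,
) -> pd.Series:
    """Per-gene NB dispersion alpha by method of moments, trend-shrunk.

    Raw estimate on normalized counts: alpha_hat = max(0, (s2 - m)/m^2)
    with m the grand mean and s2 the within-group pooled sample variance.
    A lowess mean-dispersion trend (fitted on the raw scale against log
    mean) then acts as a floor, and only a (1 - trend_weight) share of each
    gene's positive excess over the trend is kept:

        alpha = trend + (1 - trend_weight) * max(raw - trend, 0)

    Never shrinking below the trend guards the Wald test against the
    small-sample underestimation that inflates its tails; ``trend_weight=0``
    disables shrinkage entirely and returns the raw estimates.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    groups = np.asarray(groups)
    m = norm.mean(axis=1)

    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in np.unique(groups):
        sel = norm[:, groups == g]
        ss += ((sel - sel.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += sel.shape[1] - 1
    if dof < 1:
        raise ValueError("need >= 2 samples in at least one group")
    s2 = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - m) / m**2
    raw = np.where(m > 0, np.maximum(raw, 0.0), 0.0)

    alpha = raw.copy()
    if trend_weight > 0:
        expressed = m > 0
        if expressed.sum() >= 10:
            fit = lowess(raw[expressed], np.log(m[expressed]),
                         frac=lowess_frac, return_sorted=False)
            trend = np.maximum(fit, 0.0)
            excess = np.maximum(raw[expressed] - trend, 0.0)
            alpha[expressed] = trend + (1.0 - trend_weight) * excess
    return pd.Series(alpha, index=counts.index, name="alpha")


@dataclass
class DEResult:
    """Per-gene two-group DE table (group B over group A, log2 scale)."""

    table: pd.DataFrame  # base_mean, log2fc, se, wald, p, q, tested
    group_a: str
    group_b: str

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def _irls_two_group(
    counts: np.ndarray,
    x: np.ndarray,
    offsets: np.ndarray,
    alpha: np.ndarray,
    ridge: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS over genes for the model log mu = offset + b0 + b1*x.

    Returns (b1, se_b1, converged); natural-log scale.  The ridge penalty
    ridge*b1^2/2 adds ``ridge`` to the b1 curvature, keeping degenerate genes
    finite; it is symmetric in the group labels so swapping groups negates
    b1 exactly.
    """
    G, n = counts.shape
    eps = 1e-8
    mean_a = np.maximum(counts[:, x == 0].mean(axis=1), eps)
    mean_b = np.maximum(counts[:, x == 1].mean(axis=1), eps)
    b0 = np.log(mean_a)
    b1 = np.log(mean_b) - np.log(mean_a)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        eta = offsets[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offsets[None, :] + (counts - mu) / mu

        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = swx  # x is 0/1 so x^2 = x
        a11, a12, a22 = sw, swx, swxx + ridge
        r1 = (w * z).sum(axis=1)
        r2 = (w * z * x).sum(axis=1)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        new_b0 = (a22 * r1 - a12 * r2) / det
        new_b1 = (a11 * r2 - a12 * r1) / det

        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = np.where(active, new_b0, b0), np.where(active, new_b1, b1)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly

    # observed-information standard error from the final weights
    eta = offsets[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    det = sw * (swx + ridge) - swx**2
    det = np.where(det <= 0, np.nan, det)
    se_b1 = np.sqrt(sw / det)
    return b1, se_b1, converged


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray | dict,
    contrast: tuple[str, str],
    alpha: pd.Series | None = None,
    factors: pd.Series | None = None,
    ridge: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> DEResult:
    """Two-group NB Wald test for ``contrast = (group_b, group_a)``,
    reporting log2 fold changes of B over A.

    Samples outside the two groups are ignored.  Genes that never exceed
    zero counts are flagged untested; non-converged fits keep their estimate
    but get a missing p.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    if isinstance(groups, pd.Series):
        groups = groups.loc[counts.columns]
    groups = np.asarray(groups)
    group_b, group_a = contrast
    keep = np.isin(groups, [group_a, group_b])
    if (groups[keep] == group_a).sum() < 2 or (groups[keep] == group_b).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts.loc[:, keep]
    x = (groups[keep] == group_b).astype(float)

    if factors is None:
        factors = size_factors(sub)
    else:
        factors = factors.loc[sub.columns]
    if alpha is None:
        alpha = estimate_dispersion(sub, groups[keep], factors=factors)
    alpha_v = np.maximum(np.asarray(alpha.loc[sub.index], dtype=float), 0.0)

    mat = sub.to_numpy(dtype=float)
    tested = mat.sum(axis=1) > 0
    norm = mat / factors.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    offsets = np.log(factors.to_numpy())
    b1 = np.full(mat.shape[0], np.nan)
    se = np.full(mat.shape[0], np.nan)
    conv = np.zeros(mat.shape[0], dtype=bool)
    if tested.any():
        b1_t, se_t, conv_t = _irls_two_group(
            mat[tested], x, offsets, alpha_v[tested], ridge, max_iter, tol)
        b1[tested], se[tested], conv[tested] = b1_t, se_t, conv_t
        n_nc = int((~conv_t).sum())
        if n_nc:
            log.warning("nb_wald_test: %d gene(s) did not converge", n_nc)

    log2fc = b1 / LN2
    se2 = se / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = log2fc / se2
    p = np.where(np.isfinite(wald), 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
    p = np.where(tested & conv, p, np.nan)

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se2,
            "wald": wald,
            "p": p,
            "q": q,
            "tested": tested & conv,
        },
        index=sub.index,
    )
    return DEResult(table=table, group_a=group_a, group_b=group_b)


def call_degs(de: DEResult, fdr: float = 0.05) -> tuple[set[str], set[str]]:
    """Split genes with q < fdr into (up, down) sets by log2fc sign."""
    t = de.table
    sig = t["q"] < fdr
    up = set(t.index[sig & (t["log2fc"] > 0)])
    down = set(t.index[sig & (t["log2fc"] < 0)])
    return up, down
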