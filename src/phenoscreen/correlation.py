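"""Trait-expression correlation screen with BH-adjusted significance flags.

For each (trait, gene) pair within one tissue x genotype panel the screen
reports the Spearman rank correlation (the headline statistic), the Pearson
coefficient, the regression t-test of rho != 0 and Benjamini-Hochberg
adjusted p-values over the panel's whole trait x gene family.  Flags follow
the panel annotation convention: tilde for unadjusted p < 0.05, star for
adjusted p < 0.1.  CAG-repeat counts or transgene expression enter simply as
additional traits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "pearson_r",
    "spearman_rho",
    "correlation_test",
    "bh_adjust",
    "trait_gene_screen",
]

TILDE_P = 0.05
STAR_Q = 0.1


def pearson_r(x, y) -> float:
    """Product-moment correlation, computed from centred cross-products."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / denom)


def spearman_rho(x, y) -> float:
    """Pearson correlation of average ranks (ties get the average rank).

    Equals 1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    return pearson_r(stats.rankdata(x), stats.rankdata(y))


def correlation_test(rho: float, n: int) -> tuple[float, float]:
    """Regression t-test of rho != 0: t = rho*sqrt((n-2)/(1-rho^2)),
    two-sided p from Student t with n-2 degrees of freedom.

    |rho| = 1 is returned as the limiting case (t = +/-inf, p = 0).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho outside [-1, 1]")
    if abs(rho) == 1.0:
        return float(np.sign(rho) * np.inf), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_columns(df: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, df.to_numpy(dtype=float))


def _corr_matrix(xc: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlations of one centred vector against each column of Y."""
    Yc = Y - Y.mean(axis=0, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ Yc) / denom


def trait_gene_screen(
    traits: pd.DataFrame,
    expression: pd.DataFrame,
    tissue: str = "striatum",
    genotype: str = "mut",
    min_n: int = 5,
    tilde_p: float = TILDE_P,
    star_q: float = STAR_Q,
) -> pd.DataFrame:
    """Correlate every trait column against every gene column.

    ``traits``: animals x trait columns (may contain NaN); ``expression``:
    animals x gene columns (complete).  Animals are matched on the index;
    pairs with fewer than ``min_n`` overlapping animals are skipped with a
    logged count.  BH adjustment spans all tests of this call, i.e. one
    (tissue, genotype) family.
    """
    shared = traits.index.intersection(expression.index)
    expr = expression.loc[shared]
    rows = []
    n_skipped = 0
    for trait in traits.columns:
        tvals = traits.loc[shared, trait]
        ok = tvals.notna().to_numpy()
        n = int(ok.sum())
        if n < min_n:
            n_skipped += len(expr.columns)
            continue
        sub = expr.iloc[ok]
        x = tvals.to_numpy(dtype=float)[ok]
        Y = sub.to_numpy(dtype=float)
        xr = stats.rankdata(x)
        Yr = np.apply_along_axis(stats.rankdata, 0, Y)
        r_all = _corr_matrix(x - x.mean(), Y)
        rho_all = _corr_matrix(xr - xr.mean(), Yr)
        for j, gene in enumerate(expr.columns):
            rho = rho_all[j]
            if not np.isfinite(rho) or not np.isfinite(r_all[j]):
                n_skipped += 1
                continue
            t, p = correlation_test(float(np.clip(rho, -1, 1)), n)
            rows.append((tissue, genotype, trait, gene, n,
                         float(rho), float(r_all[j]), t, p))
    if n_skipped:
        log.warning("trait_gene_screen: %d pair(s) skipped (overlap < %d or constant)",
                    n_skipped, min_n)
    res = pd.DataFrame(rows, columns=[
        "tissue", "genotype", "trait", "gene", "n", "rho", "r", "t", "p"])
    if res.empty:
        return res.assign(q=[], tilde=[], star=[])
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["tilde"] = res["p"] < tilde_p
    res["star"] = res["q"] < star_q
    return res
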