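"""Severity gene sets and their progression across an allelic series.

Pairwise DE between extreme performers and pooled wild types defines four
primary sets — genes more down- or upregulated in "poor" or in "good"
mutants — plus two "rest" sets (genes altered vs wild type in both mutant
groups in the same direction but not different between poor and good).  The
sets are then scored against external CAG-length x age DE tables by their
presence among the top-N same-direction genes, and progression is
summarized as the rank correlation of presence with CAG length (at fixed
age) and with age (at fixed CAG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import spearman_rho
from .diffexpr import DEResult

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetPartition",
    "partition_gene_sets",
    "top_deg_presence",
    "progression_profile",
    "hypergeometric_ora",
]

DEFAULT_N_TOP = 684  # top-DEG cut used for the external series comparison


@dataclass
class GeneSetPartition:
    down_poor: set[str] = field(default_factory=set)
    down_good: set[str] = field(default_factory=set)
    up_poor: set[str] = field(default_factory=set)
    up_good: set[str] = field(default_factory=set)
    rest_down: set[str] = field(default_factory=set)
    rest_up: set[str] = field(default_factory=set)
    conflicts: set[str] = field(default_factory=set)

    def primary(self) -> dict[str, set[str]]:
        return {
            "down_poor": self.down_poor,
            "down_good": self.down_good,
            "up_poor": self.up_poor,
            "up_good": self.up_good,
        }

    def all_sets(self) -> dict[str, set[str]]:
        return {**self.primary(), "rest_down": self.rest_down, "rest_up": self.rest_up}

    def direction(self, name: str) -> int:
        return -1 if name.startswith(("down", "rest_down")) else 1


def partition_gene_sets(
    de_poor_wt: DEResult,
    de_good_wt: DEResult,
    de_poor_good: DEResult,
    fdr: float = 0.05,
    by: str = "lfc",
) -> GeneSetPartition:
    """Four-way severity partition plus "rest" sets.

    Candidates differ between poor and good (q < fdr in the poor-vs-good
    contrast) AND vs wild type in at least one mutant contrast.  Direction
    is the sign of the significant vs-wt fold change (genes significant in
    both with opposite signs are excluded and logged).  A candidate belongs
    to the "poor" branch when its wt-relative change is deeper in the poor
    contrast — by |log2fc| (``by='lfc'``, default) or by smaller p
    (``by='pvalue'``).  Rest sets: q < fdr vs wt in BOTH mutant contrasts,
    same sign, and q >= fdr between poor and good.
    """
    tp, tg, tpg = de_poor_wt.table, de_good_wt.table, de_poor_good.table
    if not (tp.index.equals(tg.index) and tp.index.equals(tpg.index)):
        raise ValueError("the three DE results must share one gene universe")
    if by not in ("lfc", "pvalue"):
        raise ValueError("by must be 'lfc' or 'pvalue'")

    part = GeneSetPartition()
    sig_p = tp["q"] < fdr
    sig_g = tg["q"] < fdr
    sig_pg = tpg["q"] < fdr

    for gene in tp.index:
        sp, sg = bool(sig_p.loc[gene]), bool(sig_g.loc[gene])
        if not (sp or sg):
            continue
        lp, lg = tp.at[gene, "log2fc"], tg.at[gene, "log2fc"]
        if sp and sg and np.sign(lp) != np.sign(lg):
            part.conflicts.add(gene)
            continue
        direction = np.sign(lp) if sp else np.sign(lg)
        if direction == 0:
            continue
        if bool(sig_pg.loc[gene]):
            if by == "lfc":
                poorer = abs(lp) > abs(lg)
            else:
                poorer = tp.at[gene, "p"] < tg.at[gene, "p"]
            name = ("down_" if direction < 0 else "up_") + ("poor" if poorer else "good")
            getattr(part, name).add(gene)
        elif sp and sg:
            (part.rest_down if direction < 0 else part.rest_up).add(gene)
    if part.conflicts:
        log.warning("partition_gene_sets: %d gene(s) excluded for conflicting "
                    "vs-wt directions", len(part.conflicts))
    return part


def _ranked_direction(cell_table: pd.DataFrame, direction: int) -> pd.DataFrame:
    sub = cell_table[np.sign(cell_table["log2fc"]) == direction]
    return sub.sort_values(
        ["p", "log2fc", "gene"],
        ascending=[True, False, True],
        key=lambda c: c.abs() if c.name == "log2fc" else c,
    )


def top_deg_presence(
    gene_set: set[str],
    cell_table: pd.DataFrame,
    n_top: int = DEFAULT_N_TOP,
    direction: int = -1,
) -> float:
    """Presence % of ``gene_set`` among the top-``n_top`` same-direction
    genes of one ranked DE table.

    Ranking: ascending p, ties broken by |log2fc| descending then gene id.
    The denominator is the set size; set members absent from the table count
    as not present.  If fewer than ``n_top`` genes change in the requested
    direction, the available genes are used with a logged warning.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    if direction not in (-1, 1):
        raise ValueError("direction must be +/-1")
    ranked = _ranked_direction(cell_table, direction)
    if len(ranked) < n_top:
        log.warning("top_deg_presence: only %d genes in direction %+d (< %d)",
                    len(ranked), direction, n_top)
    top = set(ranked["gene"].head(n_top))
    if not (gene_set & set(cell_table["gene"])):
        log.warning("top_deg_presence: gene set disjoint from the table universe")
    return 100.0 * len(gene_set & top) / len(gene_set)


def progression_profile(
    partition: GeneSetPartition,
    series: dict[tuple[int, int], pd.DataFrame],
    n_top: int = DEFAULT_N_TOP,
) -> tuple[pd.DataFrame, dict]:
    """Presence of each non-empty set in every (cag, age) cell, plus
    monotonicity summaries.

    Down-regulated sets are scored against the down-direction lists and up
    sets against up.  Monotonicity: Spearman rho of presence vs CAG order at
    each age and vs age at each CAG (NaN when fewer than 3 cells).
    """
    rows = []
    for name, members in partition.all_sets().items():
        if not members:
            continue
        direction = -1 if "down" in name else 1
        for (cag, age), table in sorted(series.items()):
            rows.append({
                "set": name, "cag": cag, "age": age, "direction": direction,
                "presence": top_deg_presence(members, table, n_top, direction),
            })
    profile = pd.DataFrame(rows)

    mono: dict = {"vs_cag": {}, "vs_age": {}}
    for name, grp in profile.groupby("set"):
        mono["vs_cag"][name] = {}
        mono["vs_age"][name] = {}
        for age, sub in grp.groupby("age"):
            sub = sub.sort_values("cag")
            mono["vs_cag"][name][int(age)] = (
                _safe_rho(sub["cag"], sub["presence"]))
        for cag, sub in grp.groupby("cag"):
            sub = sub.sort_values("age")
            mono["vs_age"][name][int(cag)] = (
                _safe_rho(sub["age"], sub["presence"]))
    return profile, mono


def _safe_rho(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(set(x)) < 2 or len(set(y)) < 2:
        return float("nan")
    return spearman_rho(x, y)


def hypergeometric_ora(
    gene_set: set[str],
    annotation: set[str],
    universe: set[str],
    ease: bool = False,
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation of ``annotation`` in
    ``gene_set`` against ``universe``: P(X >= k).

    ``ease=True`` applies the conservative EASE convention, replacing the
    observed overlap k by max(k - 1, 1) before computing the tail (k = 0
    still gives p = 1).
    """
    stray = (gene_set | annotation) - universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)[:5]}")
    N, K, n = len(universe), len(annotation), len(gene_set)
    k = len(gene_set & annotation)
    k_eff = max(k - 1, 1) if (ease and k > 0) else k
    if k_eff == 0:
        return k, 1.0
    p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
    return k, min(p, 1.0)
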