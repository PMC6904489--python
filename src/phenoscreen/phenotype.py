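"""Trait derivations, genotype contrasts, Z-scores and performer labels.

The classification mirrors the study design: the three traits entering the
composite (rotarod latency, feet-clasping duration, weight) are measured at
weeks 11 and 13, each measurement is oriented so that a positive score means
better performance, standardized within genotype x trait x timepoint, and the
k animals per genotype with the best (worst) composite are called "good"
("poor") performers.  The composite orders animals by the count of positive
minus negative scores first and by the mean Z-score second.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "TraitOrientation",
    "progression_rate",
    "cv_summary",
    "mann_whitney",
    "zscore_traits",
    "classify_performers",
]


@dataclass(frozen=True)
class TraitOrientation:
    """Sign convention for one trait: +1 if larger = better performance."""

    name: str
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


DEFAULT_ORIENTATIONS = (
    TraitOrientation("rotarod", 1),
    TraitOrientation("clasping", -1),
    TraitOrientation("weight", 1),
)


def progression_rate(table: pd.DataFrame, trait: str, t_late: str, t_early: str) -> pd.Series:
    """Per-animal progression Delta = value(t_late) - value(t_early).

    Animals missing either timepoint get NaN; the count of dropped animals is
    logged so downstream exclusion is visible.
    """
    if trait not in set(table["trait"]):
        raise KeyError(f"unknown trait {trait!r}")
    sub = table[table["trait"] == trait]
    tps = set(sub["timepoint"])
    for tp in (t_late, t_early):
        if tp not in tps:
            raise KeyError(f"unknown timepoint {tp!r} for trait {trait!r}")
    wide = sub.pivot(index="animal_id", columns="timepoint", values="value")
    delta = (wide[t_late] - wide[t_early]).rename(f"{trait}_delta")
    n_missing = int(delta.isna().sum())
    if n_missing:
        log.warning("progression_rate(%s): %d animal(s) missing a timepoint", trait, n_missing)
    return delta


def cv_summary(
    table: pd.DataFrame, traits: list[str], genotype: str, timepoint: str | None = None
) -> tuple[pd.Series, dict[str, float]]:
    """Per-trait coefficient of variation (sample s.d./mean, %) and its
    median/IQR across traits for one genotype.

    Traits with mean 0 get NaN CV and are flagged in the log, not dropped
    silently.
    """
    sub = table[table["genotype"] == genotype]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    cvs = {}
    for trait in traits:
        vals = sub.loc[sub["trait"] == trait, "value"].dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"trait {trait!r}: need >= 2 values for a CV")
        mean = vals.mean()
        if mean == 0:
            log.warning("cv_summary: trait %r has mean 0; CV undefined", trait)
            cvs[trait] = np.nan
            continue
        cvs[trait] = 100.0 * vals.std(ddof=1) / abs(mean)
    cv_series = pd.Series(cvs, name="cv_percent")
    finite = cv_series.dropna().to_numpy()
    summary = {
        "median": float(np.median(finite)),
        "q25": float(np.quantile(finite, 0.25)),
        "q75": float(np.quantile(finite, 0.75)),
    }
    return cv_series, summary


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j (+0.5 per tie)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)

def _exact_null_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U by enumeration of rank assignments (no ties)."""
    counts = np.zeros(n * m + 1, dtype=np.int64)
    ranks = np.arange(1, n + m + 1)
    for combo in itertools.combinations(range(n + m), n):
        r = ranks[list(combo)]
        u = r.sum() - n * (n + 1) / 2
        counts[int(u)] += 1
    return counts


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; exact p by enumeration for n+m <= 12 without
    ties, normal approximation with tie correction otherwise.

    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m

    if n + m <= 12 and not has_ties:
        counts = _exact_null_counts(n, m)
        total = counts.sum()
        ui = int(round(u))
        if alternative == "greater":
            p = counts[ui:].sum() / total
        elif alternative == "less":
            p = counts[: ui + 1].sum() / total
        else:
            lo = min(ui, n * m - ui)
            p = (counts[: lo + 1].sum() + counts[n * m - lo:].sum()) / total
        return u, float(min(p, 1.0))

    # normal approximation with tie correction (no continuity correction, so
    # identical samples give z = 0 and p = 1 exactly)
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n + m) * (n + m - 1))
    sigma2 = n * m / 12.0 * (n + m + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(sigma2)
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return u, float(min(p, 1.0))


def zscore_traits(
    table: pd.DataFrame,
    orientations=DEFAULT_ORIENTATIONS,
    group_by: tuple[str, ...] = ("genotype",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oriented Z-scores ((value - average)/standard deviation) per
    measurement, standardized within group x trait x timepoint.

    Returns (long Z table, per-animal summary with n_pos, n_neg, n_zero,
    mean_z and completeness).  Only animals with every trait x timepoint cell
    enter the summary as complete.
    """
    orient = {o.name: o.orientation for o in orientations}
    missing = set(orient) - set(table["trait"])
    if missing:
        raise KeyError(f"traits not in table: {sorted(missing)}")
    sub = table[table["trait"].isin(orient)].copy()
    sub["oriented"] = sub["value"] * sub["trait"].map(orient)

    keys = list(group_by) + ["trait", "timepoint"]
    zs = []
    for gkey, grp in sub.groupby(keys, sort=True):
        vals = grp["oriented"]
        ok = vals.notna()
        if ok.sum() < 3:
            raise ValueError(f"standardization group {gkey}: fewer than 3 animals")
        sd = vals[ok].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"standardization group {gkey}: zero standard deviation")
        z = (vals - vals[ok].mean()) / sd
        zs.append(pd.DataFrame({
            "animal_id": grp["animal_id"], "genotype": grp["genotype"],
            "trait": grp["trait"], "timepoint": grp["timepoint"], "z": z,
        }))
    ztable = pd.concat(zs, ignore_index=True)

    n_cells = sub.groupby("trait")["timepoint"].nunique().sum()
    summaries = []
    for (aid, gt), grp in ztable.groupby(["animal_id", "genotype"], sort=True):
        z = grp["z"].dropna()
        summaries.append({
            "animal_id": aid, "genotype": gt,
            "n_pos": int((z > 0).sum()), "n_neg": int((z < 0).sum()),
            "n_zero": int((z == 0).sum()), "mean_z": float(z.mean()) if len(z) else np.nan,
            "n_measurements": int(len(z)),
            "complete": bool(len(z) == n_cells),
        })
    summary = pd.DataFrame(summaries)
    return ztable, summary


def classify_performers(summary: pd.DataFrame, k: int = 4) -> pd.Series:
    """Label the k best/worst animals per genotype good/poor, rest average.

    Ordering within genotype: (n_pos - n_neg) descending, then mean_z
    descending, then animal_id ascending (deterministic tie-break).  Animals
    with incomplete trait data are excluded from ranking and labelled
    average.
    """
    labels = pd.Series("average", index=summary["animal_id"], name="label", dtype=object)
    for gt, grp in summary.groupby("genotype"):
        ranked = grp[grp["complete"]].copy()
        n_excl = len(grp) - len(ranked)
        if n_excl:
            log.warning("classify_performers: %d incomplete %s animal(s) excluded", n_excl, gt)
        if k > len(ranked) // 2:
            raise ValueError(f"k={k} too large for {len(ranked)} ranked {gt} animals")
        ranked["net_pos"] = ranked["n_pos"] - ranked["n_neg"]
        ranked = ranked.sort_values(
            ["net_pos", "mean_z", "animal_id"], ascending=[False, False, True]
        )
        labels.loc[ranked["animal_id"].head(k)] = "good"
        labels.loc[ranked["animal_id"].tail(k)] = "poor"
    return labels
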