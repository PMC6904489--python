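"""Seeded simulation studies that quantify the pipeline's behaviour.

Each function runs the relevant stage(s) on synthetic data with planted
ground truth and returns summary numbers: oracle agreement for the exact
statistics, recovery of the planted severity ranking by the performer
classification, calibration and power of the correlation screen and of the
NB Wald stage, and the progression behaviour of planted gene sets.  The
replicate counts and problem sizes are the study conditions documented in
docs/methods.md; everything is driven by one integer seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .correlation import bh_adjust, pearson_r, spearman_rho, trait_gene_screen
from .diffexpr import call_degs, nb_wald_test, size_factors
from .genesets import GeneSetPartition, hypergeometric_ora, progression_profile
from .phenotype import classify_performers, mann_whitney, zscore_traits
from .simulate import (
    SimulationConfig,
    TraitSpec,
    generate_cohort,
    generate_counts,
    generate_external_series,
)

__all__ = [
    "oracle_equivalence",
    "classification_recovery",
    "screen_null_calibration",
    "screen_power",
    "de_null_calibration",
    "de_power",
    "de_label_swap_deviation",
    "progression_study",
]


def study_traits(loading_scale: float = 2.0, noise: float = 1.0):
    """The three-trait battery at a chosen planted signal-to-noise."""
    return (
        TraitSpec("rotarod", 1, 220.0, -90.0, 20.0 * loading_scale, 20.0 * noise, -15.0),
        TraitSpec("clasping", -1, 4.0, 55.0, -12.0 * loading_scale, 12.0 * noise, 20.0),
        TraitSpec("weight", 1, 27.5, -3.0, 0.8 * loading_scale, 0.8 * noise, -0.5),
    )


# ---------------------------------------------------------------------------
# exact statistics vs independent oracles


def _mw_exact_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = sum(xi > yj for xi in x for yj in y)
    stat_low = min(u_obs, n * m - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        uu = sum(xi > yj for xi in xs for yj in ys)
        count += min(uu, n * m - uu) <= stat_low
        total += 1
    return count / total


def oracle_equivalence(seed: int, n_instances: int = 100) -> dict[str, float]:
    """Max |implementation - oracle| over random instances, plus the worked
    closed-form cases (returned so callers can assert them)."""
    rng = np.random.default_rng(seed)
    err = {k: 0.0 for k in ("spearman", "pearson", "bh", "mann_whitney",
                            "hypergeometric")}

    for _ in range(n_instances):
        n = int(rng.integers(4, 30))
        x, y = rng.normal(size=(2, n))
        if rng.random() < 0.5:
            x, y = np.round(x), np.round(y)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        err["spearman"] = max(err["spearman"], abs(
            spearman_rho(x, y) - sps.spearmanr(x, y).statistic))
        err["pearson"] = max(err["pearson"], abs(
            pearson_r(x, y) - np.corrcoef(x, y)[0, 1]))
        p = rng.uniform(size=int(rng.integers(1, 50)))
        err["bh"] = max(err["bh"], float(np.max(np.abs(
            bh_adjust(p) - multipletests(p, method="fdr_bh")[1]))))

    for _ in range(n_instances):
        n, m = (int(v) for v in rng.integers(1, 6, size=2))
        pooled = rng.permutation(np.arange(1.0, n + m + 1))
        xs, ys = pooled[:n], pooled[n:]
        _, p_impl = mann_whitney(xs, ys)
        err["mann_whitney"] = max(err["mann_whitney"],
                                  abs(p_impl - _mw_exact_oracle(xs, ys)))

    for _ in range(n_instances):
        N = int(rng.integers(5, 16))
        universe = [f"u{i}" for i in range(N)]
        annotation = set(rng.choice(universe, size=int(rng.integers(1, N + 1)),
                                    replace=False))
        gene_set = set(rng.choice(universe, size=int(rng.integers(1, N + 1)),
                                  replace=False))
        k, p_impl = hypergeometric_ora(gene_set, annotation, set(universe))
        total = 0.0
        from math import comb
        for j in range(k, min(len(annotation), len(gene_set)) + 1):
            if len(gene_set) - j <= N - len(annotation):
                total += (comb(len(annotation), j)
                          * comb(N - len(annotation), len(gene_set) - j))
        p_oracle = total / comb(N, len(gene_set)) if k > 0 else 1.0
        err["hypergeometric"] = max(err["hypergeometric"], abs(p_impl - p_oracle))

    # worked closed-form cases
    err["worked_spearman"] = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    err["worked_bh_max"] = float(bh_adjust([0.01, 0.02, 0.03, 0.04]).max())
    err["worked_mw_p"] = mann_whitney([1, 2, 3], [4, 5, 6])[1]
    err["worked_hypergeom_p"] = hypergeometric_ora(
        {"u0", "u1", "u2", "u10"}, {f"u{i}" for i in range(5)},
        {f"u{i}" for i in range(20)})[1]
    return err


# ---------------------------------------------------------------------------
# classification recovery


def classification_recovery(seed: int, n_reps: int = 200, k: int = 4) -> dict:
    """How often the k='poor' label set overlaps the k lowest planted
    severities by >= k-1 animals, across seeded cohorts."""
    hits = 0
    overlaps = []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed + rep, traits=study_traits(),
                               n_genes=10, n_signature=0)
        phen, truth = generate_cohort(cfg)
        _, summary = zscore_traits(phen)
        labels = classify_performers(summary, k=k)
        poor = set(labels[labels == "poor"].index) & set(truth.severity)
        sev = pd.Series(truth.severity)
        lowest = set(sev.nsmallest(k).index)
        overlap = len(poor & lowest)
        overlaps.append(overlap)
        hits += overlap >= k - 1
    return {"rate": hits / n_reps, "mean_overlap": float(np.mean(overlaps)),
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# correlation screen calibration and power


def _screen_once(cfg: SimulationConfig, genotype: str):
    phen, truth = generate_cohort(cfg)
    samples = phen.drop_duplicates("animal_id")[["animal_id", "genotype"]]
    counts, _ = generate_counts(truth, samples, cfg)
    factors = size_factors(counts)
    expr = np.log2(counts / factors + 1.0).T
    keep = phen[phen["genotype"] == genotype]
    traits = keep.assign(col=keep["trait"] + "_" + keep["timepoint"]).pivot(
        index="animal_id", columns="col", values="value")
    res = trait_gene_screen(traits, expr.loc[traits.index], genotype=genotype)
    return res, truth


def screen_null_calibration(seed: int, n_reps: int = 200,
                            n_genes: int = 40) -> dict:
    """Tilde-flag (p < 0.05) rate on cohorts with no planted expression
    signal; should sit at the nominal level."""
    tilde = total = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed + rep, traits=study_traits(),
                               n_genes=n_genes, n_signature=0)
        res, _ = _screen_once(cfg, "mut")
        tilde += int(res["tilde"].sum())
        total += len(res)
    return {"tilde_rate": tilde / total, "n_tests": total, "n_reps": n_reps}


def screen_power(seed: int, n_reps: int = 20, n_genes: int = 200,
                 n_signature: int = 20) -> dict:
    """Star-flag (q < 0.1) sensitivity for severity-linked gene x trait
    pairs on planted cohorts, plus the wild-type subset star rate."""
    sens, wt_rates, null_rates = [], [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed + rep, traits=study_traits(),
                               n_genes=n_genes, n_signature=n_signature,
                               severity_fraction=1.0, good_linked_fraction=0.0)
        res, truth = _screen_once(cfg, "mut")
        sig = res["gene"].isin(truth.severity_genes)
        sens.append(res.loc[sig, "star"].mean())
        null_rates.append(res.loc[~sig, "star"].mean())
        res_wt, _ = _screen_once(cfg, "wt")
        sig_wt = res_wt["gene"].isin(truth.severity_genes)
        wt_rates.append(res_wt.loc[sig_wt, "star"].mean())
    return {"sensitivity": float(np.mean(sens)),
            "null_star_rate": float(np.mean(null_rates)),
            "wt_star_rate": float(np.mean(wt_rates)),
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# differential-expression calibration and power


def _nb_matrix(rng, mean, alpha, shape):
    if alpha == 0:
        return rng.poisson(mean, size=shape)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=shape)


def _sim_counts(rng, n_genes, n_per_group, alpha, base_mean=100.0,
                planted_frac=0.0, planted_log2fc=0.0):
    mean = np.full((n_genes, 2 * n_per_group), float(base_mean))
    n_planted = int(round(planted_frac * n_genes))
    mean[:n_planted, n_per_group:] *= 2.0 ** planted_log2fc
    counts = pd.DataFrame(
        _nb_matrix(rng, mean, alpha, mean.shape),
        index=[f"g{i:05d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_group)])
    groups = pd.Series(["a"] * n_per_group + ["b"] * n_per_group,
                       index=counts.columns)
    planted = set(counts.index[:n_planted])
    return counts, groups, planted


def de_null_calibration(seed: int, n_reps: int = 20, n_genes: int = 2000,
                        n_per_group: int = 4, alpha: float = 0.2) -> dict:
    """Raw p < 0.05 fraction on NB data with no planted effects."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_reps):
        counts, groups, _ = _sim_counts(rng, n_genes, n_per_group, alpha)
        res = nb_wald_test(counts, groups, ("b", "a"))
        p = res.table["p"].dropna()
        fracs.append(float((p < 0.05).mean()))
    return {"p05_fraction": float(np.mean(fracs)), "n_reps": n_reps}


def de_power(seed: int, n_reps: int = 20, n_genes: int = 2000,
             n_per_group: int = 4, alpha: float = 0.2,
             planted_frac: float = 0.1, planted_log2fc: float = 2.0) -> dict:
    """False-discovery proportion and sensitivity at q < 0.05 with planted
    fold changes, plus the mean estimated log2fc of the planted genes."""
    rng = np.random.default_rng(seed)
    fdps, sens, lfcs = [], [], []
    for _ in range(n_reps):
        counts, groups, planted = _sim_counts(
            rng, n_genes, n_per_group, alpha,
            planted_frac=planted_frac, planted_log2fc=planted_log2fc)
        res = nb_wald_test(counts, groups, ("b", "a"))
        up, down = call_degs(res, fdr=0.05)
        called = up | down
        fdps.append(len(called - planted) / max(len(called), 1))
        sens.append(len(called & planted) / len(planted))
        lfcs.append(float(res.table.loc[sorted(planted), "log2fc"].mean()))
    return {"fdp": float(np.mean(fdps)), "sensitivity": float(np.mean(sens)),
            "mean_planted_log2fc": float(np.mean(lfcs)), "n_reps": n_reps}


def de_label_swap_deviation(seed: int, n_genes: int = 500,
                            n_per_group: int = 4) -> float:
    """Max |log2fc(b,a) + log2fc(a,b)| — the label-swap antisymmetry."""
    rng = np.random.default_rng(seed)
    counts, groups, _ = _sim_counts(rng, n_genes, n_per_group, 0.2,
                                    planted_frac=0.1, planted_log2fc=1.5)
    fwd = nb_wald_test(counts, groups, ("b", "a"))
    rev = nb_wald_test(counts, groups, ("a", "b"))
    dev = (fwd.table["log2fc"] + rev.table["log2fc"]).abs()
    return float(dev.dropna().max())


# ---------------------------------------------------------------------------
# gene-set progression


def progression_study(seed: int, n_genes: int = 2000, set_size: int = 100,
                      n_top: int = 150) -> dict:
    """Planted progressive vs null sets on a synthetic allelic series.

    Returns the mean presence-vs-CAG Spearman rho of the progressive set,
    the null set's per-cell maximum deviation from the uniform expectation
    100*n_top/G in units of its binomial standard error, and both presence
    means.
    """
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_signature=0)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    progressive = set(genes[:set_size])
    null_set = set(genes[set_size:2 * set_size])
    part = GeneSetPartition(down_poor=progressive, down_good=null_set)
    cags, ages = (80, 92, 111, 140, 175), (2, 6, 10)
    grid = [(c, a) for c in cags for a in ages]
    scaling = {(c, a): 0.15 + 0.15 * ci + 0.1 * ai
               for ci, c in enumerate(cags) for ai, a in enumerate(ages)}
    series = generate_external_series({"down_poor": (progressive, -1)}, grid,
                                      scaling, cfg, effect_scale=2.5)
    profile, mono = progression_profile(part, series, n_top=n_top)

    rhos = [v for v in mono["vs_cag"]["down_poor"].values() if v == v]
    expected = 100.0 * n_top / n_genes
    p_unif = n_top / n_genes
    se_cell = 100.0 * np.sqrt(p_unif * (1 - p_unif) / set_size)
    null_pres = profile.loc[profile["set"] == "down_good", "presence"]
    max_dev_se = float((null_pres - expected).abs().max() / se_cell)
    return {
        "progressive_rho_mean": float(np.mean(rhos)),
        "null_max_dev_se": max_dev_se,
        "progressive_presence_mean": float(
            profile.loc[profile["set"] == "down_poor", "presence"].mean()),
        "null_presence_mean": float(null_pres.mean()),
        "uniform_expectation": expected,
    }
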