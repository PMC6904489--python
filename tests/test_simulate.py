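"""Generator correctness: determinism, planted structure, NB moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoscreen.simulate import (
    SimulationConfig,
    TraitSpec,
    generate_cohort,
    generate_counts,
    generate_external_series,
)


def _flat_traits(loading, noise):
    return (
        TraitSpec("t1", 1, 10.0, -2.0, loading, noise),
        TraitSpec("t2", -1, 5.0, 1.0, -loading, noise),
    )


class TestCohort:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=11, n_genes=50, n_signature=5)
        p1, t1 = generate_cohort(cfg)
        p2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        assert t1.to_json_dict() == t2.to_json_dict()

    def test_null_loadings_no_trait_severity_correlation(self):
        cfg = SimulationConfig(
            seed=3, n_mut=200, traits=_flat_traits(0.0, 1.0), n_genes=10, n_signature=0)
        phen, truth = generate_cohort(cfg)
        sev = pd.Series(truth.severity)
        sub = phen[(phen["genotype"] == "mut") & (phen["trait"] == "t1")
                   & (phen["timepoint"] == "wk11")].set_index("animal_id")
        r = np.corrcoef(sub.loc[sev.index, "value"], sev)[0, 1]
        assert abs(r) < 0.15

    def test_noiseless_loading_gives_perfect_correlation(self):
        cfg = SimulationConfig(
            seed=5, traits=_flat_traits(2.0, 0.0), n_genes=10, n_signature=0)
        phen, truth = generate_cohort(cfg)
        sev = pd.Series(truth.severity)
        for trait, sign in (("t1", 1), ("t2", -1)):
            sub = phen[(phen["genotype"] == "mut") & (phen["trait"] == trait)
                       & (phen["timepoint"] == "wk11")].set_index("animal_id")
            r = np.corrcoef(sub.loc[sev.index, "value"], sev)[0, 1]
            assert r == pytest.approx(sign * 1.0, abs=1e-12)

    def test_wildtype_has_no_severity_component(self):
        cfg = SimulationConfig(seed=9, traits=_flat_traits(2.0, 0.0),
                               n_genes=10, n_signature=0)
        phen, _ = generate_cohort(cfg)
        wt = phen[(phen["genotype"] == "wt") & (phen["timepoint"] == "wk11")]
        for trait, spec in (("t1", cfg.traits[0]), ("t2", cfg.traits[1])):
            vals = wt.loc[wt["trait"] == trait, "value"]
            assert np.allclose(vals, spec.baseline)

    def test_all_timepoints_present_and_litters_assigned(self, small_cohort):
        phen, _ = small_cohort
        cells = phen.groupby("animal_id").size()
        assert (cells == cells.iloc[0]).all()
        assert phen["litter"].nunique() == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_wt=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_signature=50, n_genes=10)
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-0.1)

    def test_severity_recovery_rate(self):
        """With loading/noise = 2, a trait (averaged over its timepoints)
        recovers the latent factor (Spearman >= 0.8) in >= 90% of 200
        replicates at n = 29."""
        hits = 0
        for seed in range(200):
            cfg = SimulationConfig(seed=seed, traits=_flat_traits(2.0, 1.0),
                                   n_genes=10, n_signature=0)
            phen, truth = generate_cohort(cfg)
            sev = pd.Series(truth.severity)
            sub = (phen[(phen["genotype"] == "mut") & (phen["trait"] == "t1")]
                   .groupby("animal_id")["value"].mean())
            rho = stats.spearmanr(sub.loc[sev.index], sev).statistic
            hits += rho >= 0.8
        assert hits >= 180


def _samples(n_wt, n_mut):
    ids = [f"wt{i:03d}" for i in range(n_wt)] + [f"mut{i:03d}" for i in range(n_mut)]
    return pd.DataFrame({"animal_id": ids,
                         "genotype": ["wt"] * n_wt + ["mut"] * n_mut})


class TestCounts:
    def test_counts_are_nonnegative_integers_and_deterministic(self, small_config,
                                                               small_cohort):
        _, truth = small_cohort
        samples = _samples(small_config.n_wt, small_config.n_mut)
        c1, _ = generate_counts(truth, samples, small_config)
        c2, _ = generate_counts(truth, samples, small_config)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.to_numpy() >= 0).all()
        assert np.issubdtype(c1.to_numpy().dtype, np.integer)

    def test_poisson_fallback_matches_mean(self):
        """alpha = 0 degenerates to Poisson: the empirical mean of one gene
        over 10,000 draws stays within 3 s.e. of its mean parameter."""
        cfg = SimulationConfig(seed=2, n_wt=5000, n_mut=5000, n_genes=5,
                               n_signature=0, dispersion=0.0, base_mean=50.0,
                               lib_size_range=(1.0, 1.0))
        _, truth = generate_cohort(cfg)
        counts, _ = generate_counts(truth, _samples(5000, 5000), cfg)
        mean = counts.iloc[0].mean()
        se = np.sqrt(50.0 / counts.shape[1])
        assert abs(mean - 50.0) < 3 * se

    def test_planted_fold_change_recovered_at_large_n(self):
        """Unit library factors: the mutant/wt mean ratio of each signature
        gene approaches 2**planted_log2fc at n = 500 per group."""
        cfg = SimulationConfig(seed=4, n_wt=500, n_mut=500, n_genes=100,
                               n_signature=20, base_mean=100.0, dispersion=0.05,
                               lib_size_range=(1.0, 1.0), effect_log2fc=-1.0,
                               severity_slope=0.0)
        _, truth = generate_cohort(cfg)
        counts, _ = generate_counts(truth, _samples(500, 500), cfg)
        is_mut = np.array([a.startswith("mut") for a in counts.columns])
        ratio = (counts.loc[:, is_mut].mean(axis=1)
                 / counts.loc[:, ~is_mut].mean(axis=1))
        for g in truth.signature_genes:
            assert ratio[g] == pytest.approx(2.0 ** truth.planted_log2fc[g], rel=0.15)
        null_genes = [g for g in counts.index if truth.planted_log2fc[g] == 0.0]
        assert np.median(ratio[null_genes]) == pytest.approx(1.0, abs=0.05)

    def test_empirical_dispersion_consistent_with_alpha(self):
        cfg = SimulationConfig(seed=6, n_wt=200, n_mut=200, n_genes=200,
                               n_signature=0, base_mean=100.0, dispersion=0.2,
                               lib_size_range=(1.0, 1.0))
        _, truth = generate_cohort(cfg)
        counts, _ = generate_counts(truth, _samples(200, 200), cfg)
        m = counts.mean(axis=1)
        v = counts.var(axis=1, ddof=1)
        alpha_hat = np.median((v - m) / m**2)
        assert 0.1 < alpha_hat < 0.4  # within a factor of 2 of 0.2

    def test_unknown_mutant_animal_rejected(self, small_config, small_cohort):
        _, truth = small_cohort
        bad = pd.DataFrame({"animal_id": ["ghost"], "genotype": ["mut"]})
        with pytest.raises(KeyError):
            generate_counts(truth, bad, small_config)


class TestExternalSeries:
    GRID = [(80, 2), (111, 2), (175, 2)]

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=8, n_genes=500, n_signature=0)
        sets = {"s": ({"g0001", "g0002"}, -1)}
        scaling = {c: 1.0 for c in self.GRID}
        s1 = generate_external_series(sets, self.GRID, scaling, cfg)
        s2 = generate_external_series(sets, self.GRID, scaling, cfg)
        for cell in self.GRID:
            pd.testing.assert_frame_equal(s1[cell], s2[cell])

    def test_zero_scaling_is_uniform_rank_null(self):
        """With no planted effect the expected presence of any set among the
        top N same-direction genes is ~ 100*N/(G/2) per direction list."""
        from phenoscreen.genesets import top_deg_presence

        cfg = SimulationConfig(seed=10, n_genes=2000, n_signature=0)
        members = {f"g{i:04d}" for i in range(0, 400, 2)}  # 200 genes
        presences = []
        grid = [(80, a) for a in range(20)]
        series = generate_external_series(
            {"s": (members, -1)}, grid, {c: 0.0 for c in grid}, cfg)
        for cell in grid:
            presences.append(top_deg_presence(members, series[cell], 100, -1))
        # each gene lands in the down list w.p. 1/2 and in its top-100 w.p.
        # 100/(G/2) conditional; overall P(present) = 100/G per gene
        expected = 100.0 * 100 / 2000
        se = 100.0 * np.sqrt(0.05 * 0.95 / (len(members) * len(grid)))
        assert abs(np.mean(presences) - expected) < 4 * se

    def test_noiseless_monotone_scaling_gives_monotone_presence(self):
        from phenoscreen.genesets import top_deg_presence

        cfg = SimulationConfig(seed=12, n_genes=500, n_signature=0)
        members = {f"g{i:04d}" for i in range(40)}
        grid = [(80, 2), (111, 2), (175, 2)]
        scaling = {(80, 2): 0.5, (111, 2): 1.0, (175, 2): 1.5}
        series = generate_external_series({"s": (members, -1)}, grid, scaling,
                                          cfg, noise_sd=0.0)
        pres = [top_deg_presence(members, series[c], 50, -1) for c in grid]
        assert pres == sorted(pres)
        assert pres[-1] == 100.0
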