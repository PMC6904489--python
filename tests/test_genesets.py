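"""Partition rules, top-DEG presence, progression and hypergeometric ORA."""

import math

import pandas as pd
import pytest

from phenoscreen.diffexpr import DEResult
from phenoscreen.genesets import (
    GeneSetPartition,
    hypergeometric_ora,
    partition_gene_sets,
    progression_profile,
    top_deg_presence,
)
from phenoscreen.simulate import SimulationConfig, generate_external_series


def _de(genes, lfc, q):
    t = pd.DataFrame({
        "base_mean": 10.0,
        "log2fc": lfc,
        "se": 0.1,
        "wald": 0.0,
        "p": q,
        "q": q,
        "tested": True,
    }, index=pd.Index(genes, name="gene"))
    return DEResult(table=t, group_a="x", group_b="y")


class TestPartition:
    GENES = ["gA", "gB", "gC", "gD", "gE", "gF"]

    def _three_results(self):
        # gA: down vs wt in both (-2 poor, -0.5 good), poor/good significant
        #     -> down_poor
        # gB: down vs wt in both (-1.5 each), poor/good NOT significant
        #     -> rest_down
        # gC: up in both (+0.6 poor, +2.1 good), poor/good significant
        #     -> up_good
        # gD: opposite significant directions -> conflict, excluded
        # gE: significant only in good contrast (+1), poor/good significant,
        #     |lfc good| > |lfc poor| -> up_good
        # gF: nothing significant anywhere -> no set
        poor = _de(self.GENES,
                   lfc=[-2.0, -1.5, 0.6, 1.0, 0.4, 0.1],
                   q=[0.01, 0.02, 0.03, 0.01, 0.3, 0.9])
        good = _de(self.GENES,
                   lfc=[-0.5, -1.5, 2.1, -1.0, 1.0, 0.0],
                   q=[0.04, 0.02, 0.01, 0.01, 0.01, 0.9])
        pg = _de(self.GENES,
                 lfc=[-1.5, 0.0, -1.5, 2.0, -0.6, 0.1],
                 q=[0.01, 0.8, 0.02, 0.01, 0.04, 0.9])
        return poor, good, pg

    def test_hand_constructed_partition(self):
        part = partition_gene_sets(*self._three_results(), fdr=0.05)
        assert part.down_poor == {"gA"}
        assert part.rest_down == {"gB"}
        assert part.up_good == {"gC", "gE"}
        assert part.conflicts == {"gD"}
        assert part.down_good == set() and part.up_poor == set()
        assert part.rest_up == set()

    def test_primary_sets_disjoint_and_reconciled(self):
        part = partition_gene_sets(*self._three_results(), fdr=0.05)
        sets = list(part.primary().values()) + [part.rest_down, part.rest_up]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not (a & b)

    def test_pvalue_assignment_mode(self):
        poor, good, pg = self._three_results()
        part = partition_gene_sets(poor, good, pg, fdr=0.05, by="pvalue")
        # gA: p poor (0.01) < p good (0.04) -> still down_poor
        assert "gA" in part.down_poor

    def test_empty_inputs_give_empty_partition(self):
        empty = _de(self.GENES, lfc=[0.0] * 6, q=[1.0] * 6)
        part = partition_gene_sets(empty, empty, empty)
        assert all(not s for s in part.all_sets().values())

    def test_mismatched_universe_rejected(self):
        poor, good, pg = self._three_results()
        other = _de(["x1", "x2", "x3", "x4", "x5", "x6"],
                    lfc=[0.0] * 6, q=[1.0] * 6)
        with pytest.raises(ValueError, match="universe"):
            partition_gene_sets(poor, good, other)


class TestPresence:
    def _cell(self):
        return pd.DataFrame({
            "gene": ["g1", "g5", "g2", "g9", "g3", "u1", "u2"],
            "log2fc": [-1.0, -2.0, -0.5, -0.1, -0.3, 1.0, 2.0],
            "p": [0.001, 0.002, 0.003, 0.5, 0.6, 0.01, 0.02],
        })

    def test_direct_counting(self):
        # top-3 down list is [g1, g5, g2]; the set holds 4 genes, 2 present
        presence = top_deg_presence({"g1", "g2", "g3", "g4"}, self._cell(),
                                    n_top=3, direction=-1)
        assert presence == 50.0

    def test_full_containment(self):
        assert top_deg_presence({"g1", "g5"}, self._cell(), 3, -1) == 100.0

    def test_disjoint_set_warns_and_scores_zero(self, caplog):
        with caplog.at_level("WARNING"):
            presence = top_deg_presence({"zz1", "zz2"}, self._cell(), 3, -1)
        assert presence == 0.0
        assert "disjoint" in caplog.text

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            top_deg_presence(set(), self._cell(), 3, -1)

    def test_invariant_to_order_below_cut(self):
        cell = self._cell()
        swapped = cell.copy()
        # swap the p-values of the two below-cut down genes
        swapped.loc[swapped["gene"] == "g9", "p"] = 0.6
        swapped.loc[swapped["gene"] == "g3", "p"] = 0.5
        s = {"g1", "g9", "g3"}
        assert (top_deg_presence(s, cell, 3, -1)
                == top_deg_presence(s, swapped, 3, -1))


class TestProgression:
    def test_noiseless_planted_sets_saturate(self):
        """With zero noise every planted gene outranks the (excluded) null
        genes, so presence saturates at 100% in each cell."""
        cfg = SimulationConfig(seed=21, n_genes=600, n_signature=0)
        members = {f"g{i:04d}" for i in range(30)}
        part = GeneSetPartition(down_poor=set(members))
        grid = [(c, a) for c in (80, 111, 175) for a in (2, 6)]
        scaling = {(c, a): 0.3 * ci + 0.2 * ai
                   for ci, c in enumerate((80, 111, 175), 1)
                   for ai, a in enumerate((2, 6), 1)}
        series = generate_external_series({"down_poor": (members, -1)}, grid,
                                          scaling, cfg, noise_sd=0.0)
        profile, _ = progression_profile(part, series, n_top=40)
        assert set(profile["set"]) == {"down_poor"}
        assert (profile["presence"] == 100.0).all()

    def test_noisy_planted_sets_score_high_cag_monotonicity(self):
        """With unit noise and sub-saturating effects the presence of a
        planted progressive set rises with CAG length (rho >= 0.9)."""
        cfg = SimulationConfig(seed=23, n_genes=2000, n_signature=0)
        members = {f"g{i:04d}" for i in range(50)}
        part = GeneSetPartition(down_poor=set(members))
        cags = (80, 92, 111, 140, 175)
        grid = [(c, 2) for c in cags]
        scaling = {(c, 2): 0.2 + 0.15 * ci for ci, c in enumerate(cags)}
        series = generate_external_series({"down_poor": (members, -1)}, grid,
                                          scaling, cfg, noise_sd=1.0,
                                          effect_scale=2.5)
        _, mono = progression_profile(part, series, n_top=150)
        assert mono["vs_cag"]["down_poor"][2] >= 0.9

    def test_determinism(self):
        cfg = SimulationConfig(seed=22, n_genes=400, n_signature=0)
        members = {f"g{i:04d}" for i in range(20)}
        part = GeneSetPartition(up_good=set(members))
        grid = [(80, 2), (111, 2), (175, 2)]
        series = generate_external_series({"up_good": (members, 1)}, grid,
                                          {c: 1.0 for c in grid}, cfg)
        p1, m1 = progression_profile(part, series, n_top=50)
        p2, m2 = progression_profile(part, series, n_top=50)
        pd.testing.assert_frame_equal(p1, p2)
        assert repr(m1) == repr(m2)  # repr-compare: NaN-valued cells stay equal


class TestHypergeometricOra:
    UNIVERSE = {f"u{i}" for i in range(20)}

    def test_worked_tail_probability(self):
        # N=20, K=5, n=4, k=3 -> p = (C(5,3)C(15,1)+C(5,4)C(15,0))/C(20,4)
        universe = sorted(self.UNIVERSE)
        annotation = set(universe[:5])
        gene_set = set(universe[:3]) | {universe[10]}
        k, p = hypergeometric_ora(gene_set, annotation, self.UNIVERSE)
        assert k == 3
        assert p == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = sorted(self.UNIVERSE)
        k, p = hypergeometric_ora(set(universe[10:14]), set(universe[:5]),
                                  self.UNIVERSE)
        assert k == 0 and p == 1.0

    def test_ease_decrements_overlap(self):
        universe = sorted(self.UNIVERSE)
        annotation = set(universe[:5])
        gene_set = set(universe[:3]) | {universe[10]}
        _, p_plain = hypergeometric_ora(gene_set, annotation, self.UNIVERSE)
        _, p_ease = hypergeometric_ora(gene_set, annotation, self.UNIVERSE,
                                       ease=True)
        assert p_ease > p_plain  # k=3 scored as k=2

    def test_matches_enumeration_oracle(self, rng):
        """100 random small instances vs exhaustive enumeration."""
        for _ in range(100):
            N = int(rng.integers(5, 16))
            universe = [f"u{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            annotation = set(rng.choice(universe, size=K, replace=False))
            gene_set = set(rng.choice(universe, size=n, replace=False))
            k, p = hypergeometric_ora(gene_set, annotation, set(universe))
            # oracle: sum the hypergeometric pmf by direct binomials
            total = math.comb(N, n)
            expect = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= N - K) / total
            assert p == pytest.approx(expect, abs=1e-9)

    def test_stray_genes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_ora({"nope"}, set(), self.UNIVERSE)
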