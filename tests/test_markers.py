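"""Marker layer: CPM identities, filtering, BH oracle, DE power and nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_stepup

from psmatch.markers import (
    DifferentialConfig,
    DifferentialResult,
    bh_adjust,
    compare_score_panel,
    compare_sets,
    cpm,
    differential_expression,
    filter_low_expression,
)


def nb_counts(rng, mu, dispersion=0.1):
    size = 1 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def toy_counts(values, genes=None, subjects=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    subjects = subjects or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=subjects)


def groups_for(counts, n_poor):
    n = counts.shape[1]
    return pd.Series([0] * (n - n_poor) + [1] * n_poor, index=counts.columns)


class TestCpm:
    def test_single_gene_full_library(self):
        c = toy_counts([[10]])
        assert cpm(c).iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        c = toy_counts(rng.integers(0, 500, (40, 7)) + 1)
        assert np.allclose(cpm(c).sum(axis=0), 1e6)

    def test_hand_computed_3x2(self):
        c = toy_counts([[1, 4], [2, 4], [1, 2]])
        # libraries: 4 and 10
        expected = np.array([[0.25, 0.4], [0.5, 0.4], [0.25, 0.2]]) * 1e6
        assert np.allclose(cpm(c).to_numpy(), expected)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError, match="library"):
            cpm(toy_counts([[0, 5], [0, 5]]))


class TestFilter:
    def test_high_expression_kept_all_zero_removed(self):
        c = toy_counts([[1000, 1000, 1000, 1000], [0, 0, 0, 0], [1, 1, 1, 1]])
        kept = filter_low_expression(c, groups_for(c, 2))
        assert "g0" in kept.index and "g1" not in kept.index

    def test_min_group_rule_hand_enumeration(self):
        # libraries equal; CPM proportional to counts. threshold 15 CPM with
        # total 1e6 per column scaled: build counts so CPM is transparent
        base = np.array(
            [
                [100, 100, 100, 100],  # always expressed
                [100, 100, 0, 0],      # expressed in 2 subjects = min group
                [100, 0, 0, 0],        # expressed in 1 < min group
                [0, 0, 100, 100],
                [700, 800, 800, 800],  # filler keeping libraries positive
            ]
        )
        c = toy_counts(base * 1000)
        cfg = DifferentialConfig(cpm_threshold=15.0, filter_rule="min_group")
        kept = filter_low_expression(c, groups_for(c, 2), cfg)
        assert set(kept.index) == {"g0", "g1", "g3", "g4"}

    def test_mean_rule(self):
        c = toy_counts([[100, 100], [1, 1], [899, 899]])
        cfg = DifferentialConfig(cpm_threshold=15.0, filter_rule="mean")
        kept = filter_low_expression(c, groups_for(c, 1), cfg)
        # mean CPM of g1 = 1000 >= 15 still passes: threshold is on CPM scale
        assert set(kept.index) == {"g0", "g1", "g2"}

    def test_all_filtered_errors(self):
        c = toy_counts([[1, 1, 1, 1]])
        cfg = DifferentialConfig(cpm_threshold=2e6)
        with pytest.raises(ValueError, match="filter"):
            filter_low_expression(c, groups_for(c, 2), cfg)

    def test_filter_recomputed_on_subcohort(self):
        rng = np.random.default_rng(4)
        c = toy_counts(rng.integers(10, 200, (50, 20)))
        g = groups_for(c, 8)
        full = filter_low_expression(c, g)
        sub_cols = c.columns[:10]
        sub = filter_low_expression(c[sub_cols], g[sub_cols])
        # both runs used their own library sizes; shapes may differ
        assert sub.shape[1] == 10 and full.shape[1] == 20


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_stepup(self, p):
        assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestScorePanel:
    def test_constant_marker_flagged(self):
        panel = pd.DataFrame([[5.0] * 6], index=["m"], columns=[f"s{i}" for i in range(6)])
        res = compare_score_panel(panel, groups_for(panel, 3))
        assert res.table.loc["m", "flagged"]
        assert np.isnan(res.table.loc["m", "p"])

    def test_binary_marker_identical_counts_p_one(self):
        panel = pd.DataFrame([[1, 1, 0, 0, 1, 1, 0, 0]], index=["b"],
                             columns=[f"s{i}" for i in range(8)])
        res = compare_score_panel(panel, groups_for(panel, 4))
        assert res.table.loc["b", "kind"] == "binary"
        assert res.table.loc["b", "p"] == pytest.approx(1.0)

    def test_spiked_marker_power_at_n116(self):
        # effect large vs noise at 58 + 58 subjects: detected in >=90% of seeds
        hits = 0
        n = 116
        for seed in range(40):
            rng = np.random.default_rng(seed)
            g = groups_for(pd.DataFrame(np.zeros((1, n)),
                                        columns=[f"s{i}" for i in range(n)]), 58)
            vals = 100 + 25.0 * g.to_numpy() + rng.normal(0, 30, n)
            panel = pd.DataFrame([vals], index=["spike"], columns=g.index)
            res = compare_score_panel(panel, g)
            hits += bool(res.table.loc["spike", "significant"])
        assert hits >= 36

    def test_effect_direction(self):
        g = pd.Series([0, 0, 0, 1, 1, 1], index=[f"s{i}" for i in range(6)])
        panel = pd.DataFrame([[1, 2, 3, 11, 12, 13.0]], index=["up"], columns=g.index)
        res = compare_score_panel(panel, g)
        assert res.table.loc["up", "direction"] == "up"
        assert res.table.loc["up", "effect"] == pytest.approx(10.0)


class TestDifferentialExpression:
    def test_null_calibration(self):
        # pure-null NB counts: raw p < .05 in ~5% of genes
        fracs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            mu = np.outer(rng.uniform(50, 500, 400), np.ones(56))
            c = toy_counts(nb_counts(rng, mu))
            res = differential_expression(c, groups_for(c, 28))
            fracs.append((res.table["p"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_four_fold_shift_detected(self):
        # 4-fold mean shift, dispersion 0.1, 28 vs 28: FDR hit in >=90% of seeds
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            mu = np.outer(rng.uniform(50, 500, 200), np.ones(56))
            mu[0, 28:] *= 4.0  # spiked gene, poor group
            c = toy_counts(nb_counts(rng, mu))
            res = differential_expression(c, groups_for(c, 28))
            hits += bool(res.table.iloc[0]["significant"])
        assert hits >= 27

    def test_lfc_sign_and_scale(self):
        rng = np.random.default_rng(11)
        mu = np.outer(np.full(100, 200.0), np.ones(40))
        mu[0, 20:] *= 4.0
        c = toy_counts(nb_counts(rng, mu))
        res = differential_expression(c, groups_for(c, 20))
        assert res.table.iloc[0]["effect"] == pytest.approx(2.0, abs=0.5)
        assert res.table.iloc[0]["direction"] == "up"

    def test_degenerate_groups_error(self):
        c = toy_counts([[5, 5, 5]])
        with pytest.raises(ValueError, match="2 subjects"):
            differential_expression(c, pd.Series([0, 0, 1], index=c.columns))

    def test_significance_flag_matches_fdr_threshold(self):
        rng = np.random.default_rng(12)
        mu = np.outer(rng.uniform(50, 500, 300), np.ones(30))
        mu[:30, 15:] *= 3.0
        c = toy_counts(nb_counts(rng, mu))
        res = differential_expression(c, groups_for(c, 15))
        assert (res.table["significant"] == (res.table["fdr"] < 0.05)).all()


class TestCompareSets:
    def _result(self, sig, universe):
        t = pd.DataFrame(
            {"effect": 1.0, "p": 0.01, "fdr": 0.01, "direction": "up",
             "significant": [g in sig for g in universe]},
            index=pd.Index(universe),
        )
        return DifferentialResult(table=t, layer="counts")

    def test_identical_results_all_shared(self):
        u = [f"g{i}" for i in range(10)]
        a = self._result({"g1", "g2"}, u)
        comp = compare_sets(a, a)
        assert comp.shared == ["g1", "g2"]
        assert comp.pre_only == [] and comp.post_only == []
        assert comp.counts["non_significant"] == 8

    def test_disjoint_sets_additive(self):
        u = [f"g{i}" for i in range(10)]
        comp = compare_sets(self._result({"g1"}, u), self._result({"g2", "g3"}, u))
        assert comp.shared == []
        assert comp.pre_only == ["g1"] and comp.post_only == ["g2", "g3"]

    def test_partition_identity(self):
        u = [f"g{i}" for i in range(30)]
        pre = self._result({f"g{i}" for i in range(0, 12)}, u)
        post = self._result({f"g{i}" for i in range(8, 18)}, u)
        comp = compare_sets(pre, post)
        assert len(comp.shared) + len(comp.pre_only) == 12  # |pre sig|
        cats = comp.volcano["category"].value_counts()
        assert cats.sum() == 30

    def test_universe_is_intersection(self):
        pre = self._result({"g1"}, ["g0", "g1", "g2"])
        post = self._result({"g1", "g3"}, ["g1", "g2", "g3"])
        comp = compare_sets(pre, post)
        assert comp.universe_size == 2
        assert comp.shared == ["g1"] and comp.post_only == []

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="shared"):
            compare_sets(self._result(set(), ["a"]), self._result(set(), ["b"]))
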