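from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rnaedit.assoc import (
    SignificantSets,
    AssociationRecord,
    adjust_records,
    bh_adjust,
    compare_groups,
    correlate_profile,
    double_intersection,
    fisher_z_mean,
    intersect_and_test,
    permutation_intersection_test,
    significant_sets,
)


def bh_brute_force(pvals):
    """Independent step-up oracle: find the largest k with p_(k) <= k/m * q,
    expressed as adjusted p-values via the textbook min/cummin definition."""
    p = list(pvals)
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = indexed[rank_from_top]
        candidate = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


class TestCorrelateProfile:
    def test_identical_vectors_rho_one(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        feats = pd.DataFrame([score.to_numpy()], index=["f"], columns=score.index)
        (rec,) = correlate_profile(score, feats)
        assert rec.rho == pytest.approx(1.0)

    def test_rank_reversed_rho_minus_one(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        feats = pd.DataFrame([[8.0, 6.0, 4.0, 2.0]], index=["f"], columns=score.index)
        (rec,) = correlate_profile(score, feats)
        assert rec.rho == pytest.approx(-1.0)

    def test_hand_spearman(self):
        # (1,2,3,4,5) vs (2,1,4,3,5): d = (1,-1,1,-1,0), sum d^2 = 4,
        # rho = 1 - 6*4/(5*(25-1)) = 0.8
        score = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        feats = pd.DataFrame([[2.0, 1, 4, 3, 5]], index=["f"], columns=score.index)
        (rec,) = correlate_profile(score, feats)
        assert rec.rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_constant_feature_undefined(self):
        score = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        feats = pd.DataFrame([[7.0, 7, 7, 7]], index=["f"], columns=score.index)
        (rec,) = correlate_profile(score, feats)
        assert np.isnan(rec.rho)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        score = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        row = rng.normal(size=30)
        feats = pd.DataFrame([row, np.exp(row)], index=["raw", "exp"], columns=score.index)
        raw, transformed = correlate_profile(score, feats)
        assert transformed.rho == pytest.approx(raw.rho)
        assert transformed.p == pytest.approx(raw.p)

    def test_missing_values_pairwise_deleted(self):
        score = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        feats = pd.DataFrame(
            [[1.0, 2, 3, 4, np.nan]], index=["f"], columns=score.index
        )
        (rec,) = correlate_profile(score, feats)
        assert rec.rho == pytest.approx(1.0)

    def test_no_overlap_raises(self):
        score = pd.Series([1.0], index=["x"])
        feats = pd.DataFrame([[1.0]], index=["f"], columns=["y"])
        with pytest.raises(ValueError, match="overlap"):
            correlate_profile(score, feats)


class TestBHAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_brute_force(p))

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))


class TestSignificantSets:
    def records(self, rows):
        return [AssociationRecord(f, r, p, p_adj) for f, r, p, p_adj in rows]

    def test_rule_application(self):
        recs = self.records([("f1", 0.5, 0.001, 0.01)])
        sets = significant_sets(recs, rho_threshold=0.2)
        assert sets.positive == {"f1"}

    def test_small_rho_excluded_despite_significance(self):
        recs = self.records([("f1", 0.15, 0.0001, 0.001)])
        sets = significant_sets(recs, rho_threshold=0.2)
        assert sets.positive == set() and sets.negative == set()
        assert sets.universe == {"f1"}

    def test_negative_symmetric(self):
        recs = self.records([("f1", -0.5, 0.001, 0.01)])
        sets = significant_sets(recs, rho_threshold=0.2)
        assert sets.negative == {"f1"}

    def test_empty_records(self):
        sets = significant_sets([])
        assert sets.positive == set() == sets.negative == sets.universe


class TestDoubleIntersection:
    def test_identical_sets(self):
        groups = [
            SignificantSets("g", positive={"A", "B"}, negative={"C"})
            for _ in range(4)
        ]
        assert double_intersection(groups) == ({"A", "B"}, {"C"})

    def test_disjoint_sets(self):
        groups = [
            SignificantSets("g1", positive={"A"}),
            SignificantSets("g2", positive={"B"}),
        ]
        assert double_intersection(groups) == (set(), set())

    def test_four_group_example(self):
        positives = [{"A", "B", "C"}, {"A", "B"}, {"A", "B", "D"}, {"A", "B"}]
        groups = [SignificantSets(f"g{i}", positive=p) for i, p in enumerate(positives)]
        pos, _ = double_intersection(groups)
        assert pos == {"A", "B"}


class TestPermutationIntersectionTest:
    UNIVERSE = {f"u{i}" for i in range(40)}

    def test_observed_zero_gives_p_one(self):
        sets = [{"u0"}, {"u1"}]
        p = permutation_intersection_test(sets, self.UNIVERSE, n_perm=200, seed=1)
        assert p == 1.0

    def test_whole_universe_gives_p_one(self):
        sets = [set(self.UNIVERSE), set(self.UNIVERSE)]
        p = permutation_intersection_test(sets, self.UNIVERSE, n_perm=100, seed=1)
        assert p == 1.0

    def test_seeded_and_reproducible(self):
        sets = [set(list(self.UNIVERSE)[:20]), set(list(self.UNIVERSE)[:20])]
        a = permutation_intersection_test(sets, self.UNIVERSE, n_perm=500, seed=9)
        b = permutation_intersection_test(sets, self.UNIVERSE, n_perm=500, seed=9)
        assert a == b

    def test_strong_overlap_is_significant(self):
        shared = {f"u{i}" for i in range(15)}
        p = permutation_intersection_test([shared, shared], self.UNIVERSE,
                                          n_perm=999, seed=2)
        assert p < 0.01

    def test_p_at_least_one_over_b_plus_one(self):
        shared = set(self.UNIVERSE)
        p = permutation_intersection_test([shared], self.UNIVERSE, n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            permutation_intersection_test([{"zzz"}], self.UNIVERSE, n_perm=10, seed=0)

    def test_null_calibration(self):
        """Under random sets the test rejects at ~5% (conservative <= nominal)."""
        rng = np.random.default_rng(77)
        universe = [f"u{i}" for i in range(50)]
        rejections = 0
        n_rep = 400
        for rep in range(n_rep):
            sets = [
                set(rng.choice(universe, size=25, replace=False)) for _ in range(2)
            ]
            p = permutation_intersection_test(sets, set(universe),
                                              n_perm=199, seed=rep)
            rejections += p < 0.05
        rate = rejections / n_rep
        # valid (<= ~0.05 + MC noise) but not hopelessly conservative
        assert rate <= 0.08
        assert rate >= 0.01


class TestFisherZMean:
    def test_equal_values(self):
        assert fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5)

    def test_zero_and_point_eight(self):
        assert fisher_z_mean([0.0, 0.8]) == pytest.approx(0.5, abs=5e-5)

    def test_antisymmetry(self):
        for r in (0.2, 0.5, 0.9):
            assert fisher_z_mean([r, -r]) == pytest.approx(0.0, abs=1e-12)

    def test_clamps_exact_one_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            out = fisher_z_mean([1.0, 0.0])
        assert 0 < out < 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_mean([1.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_mean([])


class TestCompareGroups:
    def test_identical_distributions_no_rejection(self):
        values = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        df = compare_groups(values, labels)
        assert df.loc[0, "p"] > 0.5

    def test_fully_separated_u_zero(self):
        values = pd.Series([1.0, 2, 3, 10, 20, 30], index=list("abcdef"))
        labels = pd.Series(["lo"] * 3 + ["hi"] * 3, index=list("abcdef"))
        df = compare_groups(values, labels, comparisons=[("lo", "hi")])
        assert df.loc[0, "u_statistic"] == 0.0

    def test_empty_group_rejected(self):
        values = pd.Series([1.0, 2.0], index=list("ab"))
        labels = pd.Series(["x", "x"], index=list("ab"))
        with pytest.raises(ValueError, match="empty group"):
            compare_groups(values, labels, comparisons=[("x", "y")])

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(5)
        n_rep, rejections = 300, 0
        for _ in range(n_rep):
            values = pd.Series(rng.normal(size=40))
            labels = pd.Series(["a"] * 20 + ["b"] * 20)
            df = compare_groups(values, labels)
            rejections += df.loc[0, "p"] < 0.05
        assert 0.01 <= rejections / n_rep <= 0.09


class TestPlantedRecovery:
    def test_planted_features_recovered_with_controlled_fdr(self):
        from rnaedit.synthetic import SimulationConfig, simulate_expression

        rng = np.random.default_rng(2024)
        n = 100
        scores = pd.Series(rng.uniform(0, 30, size=n),
                           index=[f"s{i:03d}" for i in range(n)])
        config = SimulationConfig(
            seed=7, n_samples=n, n_genes=500, n_planted_positive=25,
            n_planted_negative=25, effect_size=1.5, noise_sd=0.4,
        )
        expr, truth = simulate_expression(config, scores)
        records = adjust_records(correlate_profile(scores, expr))
        sets = significant_sets(records, rho_threshold=0.2)

        planted_pos = set(truth.loc[truth.planted == "positive", "feature_id"])
        planted_neg = set(truth.loc[truth.planted == "negative", "feature_id"])
        discovered = sets.positive | sets.negative
        true_hits = (sets.positive & planted_pos) | (sets.negative & planted_neg)

        recovery = len(true_hits) / (len(planted_pos) + len(planted_neg))
        fdr = 1 - len(true_hits) / len(discovered) if discovered else 0.0
        assert recovery >= 0.9
        assert fdr <= 0.1

    def test_zero_effect_behaves_as_null(self):
        from rnaedit.synthetic import SimulationConfig, simulate_expression

        rng = np.random.default_rng(31)
        n = 60
        scores = pd.Series(rng.uniform(0, 30, size=n),
                           index=[f"s{i:03d}" for i in range(n)])
        config = SimulationConfig(
            seed=8, n_samples=n, n_genes=300, n_planted_positive=20,
            n_planted_negative=20, effect_size=0.0, noise_sd=0.4,
        )
        expr, truth = simulate_expression(config, scores)
        records = adjust_records(correlate_profile(scores, expr))
        sets = significant_sets(records)
        # with no real signal, BH keeps discoveries near zero
        assert len(sets.positive | sets.negative) <= 5


def test_intersect_and_test_report_fields():
    groups = [
        SignificantSets(f"g{i}", positive={"A", "B"}, negative={"C"},
                        universe={f"u{j}" for j in range(20)} | {"A", "B", "C"})
        for i in range(2)
    ]
    res = intersect_and_test(groups, n_perm=99, seed=3)
    assert res.common_positive == {"A", "B"}
    assert res.common_negative == {"C"}
    assert 0 < res.perm_p_positive <= 1
    assert res.n_permutations == 99
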