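"""Fractional ranks, concentration curves, and the three CI estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mchequity import (
    ConcentrationCurve,
    ci_area,
    ci_covariance,
    ci_regression,
    curve_points,
    dominance,
    fractional_rank,
    rank_outcome,
)

from conftest import random_weighted_dataset


class TestFractionalRank:
    @pytest.mark.parametrize("weights, expected", [
        ([0.25] * 4, [0.125, 0.375, 0.625, 0.875]),
        ([0.4, 0.1, 0.2, 0.3], [0.20, 0.45, 0.60, 0.85]),
        ([1.0], [0.5]),
    ])
    def test_weighted_mid_ranks(self, weights, expected):
        np.testing.assert_allclose(fractional_rank(np.array(weights)), expected)

    def test_rejects_unnormalized_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fractional_rank(np.array([0.5, 0.6]))

    def test_tied_scores_share_average_mid_rank(self):
        ranked = rank_outcome(np.ones(4), np.array([1.0, 2.0, 2.0, 3.0]),
                              np.ones(4))
        # the tied middle block spans mid-ranks 0.375 and 0.625 -> 0.5 each
        np.testing.assert_allclose(ranked.r, [0.125, 0.5, 0.5, 0.875])

    def test_tie_handling_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        wealth = np.array([3.0, 1.0, 3.0, 2.0, 3.0])
        h = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w = np.array([0.5, 1.0, 1.5, 2.0, 1.0])
        base = ci_covariance(rank_outcome(h, wealth, w)).estimate
        for _ in range(5):
            perm = rng.permutation(5)
            est = ci_covariance(rank_outcome(h[perm], wealth[perm], w[perm])).estimate
            assert est == pytest.approx(base, abs=1e-12)


class TestCurve:
    def test_individual_curve_cumulative_shares(self):
        ranked = rank_outcome(np.arange(1.0, 6.0), np.arange(5), np.ones(5))
        curve = curve_points(ranked)
        np.testing.assert_allclose(curve.L, [0, 1 / 15, 3 / 15, 6 / 15, 10 / 15, 1])

    def test_constant_outcome_tracks_line_of_equality(self):
        ranked = rank_outcome(np.full(10, 2.0), np.arange(10), np.ones(10))
        curve = curve_points(ranked)
        np.testing.assert_allclose(curve.L, curve.p, atol=1e-12)
        assert ci_area(curve).estimate == pytest.approx(0.0, abs=1e-12)

    def test_all_mass_on_richest_individual(self):
        h = np.r_[np.zeros(9), 5.0]
        ranked = rank_outcome(h, np.arange(10), np.ones(10))
        curve = curve_points(ranked)
        assert curve.L[-2] == pytest.approx(0.0)
        assert curve.L[-1] == pytest.approx(1.0)

    def test_quintile_grouping_has_six_points(self, population):
        ranked = rank_outcome(population["anc_visits"].to_numpy(float),
                              population["wealth_score"].to_numpy(),
                              population["sampling_weight"].to_numpy())
        curve = curve_points(ranked, grouping="quintile")
        np.testing.assert_allclose(curve.p, [0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert np.all(np.diff(curve.L) >= 0)

    def test_zero_mean_outcome_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            curve_points(rank_outcome(np.zeros(5), np.arange(5), np.ones(5)))


class TestEstimators:
    def test_hand_computed_example(self):
        ranked = rank_outcome(np.arange(1.0, 6.0), np.arange(5), np.ones(5))
        # 2 * cov_w(h, r) / mu = 2 * 0.4 / 3
        for est in (ci_covariance(ranked), ci_regression(ranked),
                    ci_area(curve_points(ranked))):
            assert est.estimate == pytest.approx(0.2666667, abs=1e-6)

    def test_wealth_reversal_flips_sign(self, population):
        h = population["anc_visits"].to_numpy(float)
        ws = population["wealth_score"].to_numpy()
        w = population["sampling_weight"].to_numpy()
        a = ci_covariance(rank_outcome(h, ws, w)).estimate
        b = ci_covariance(rank_outcome(h, -ws, w)).estimate
        assert a == pytest.approx(-b, abs=1e-12)

    def test_regression_standard_error_matches_statsmodels_wls(self, population):
        import statsmodels.api as sm
        from mchequity.concentration import weighted_rank_variance

        h = population["anc_visits"].to_numpy(float)[:800]
        ranked = rank_outcome(h, population["wealth_score"].to_numpy()[:800],
                              population["sampling_weight"].to_numpy()[:800])
        est = ci_regression(ranked)
        y = 2 * weighted_rank_variance(ranked) * ranked.h / ranked.mu
        X = sm.add_constant(ranked.r)
        fit = sm.WLS(y, X, weights=ranked.w).fit()
        assert est.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert est.standard_error == pytest.approx(fit.bse[1], rel=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_regression_equals_covariance_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        h, wealth, w = random_weighted_dataset(rng)
        ranked = rank_outcome(h, wealth, w)
        cov = ci_covariance(ranked).estimate
        reg = ci_regression(ranked).estimate
        assert abs(cov) <= 1.0
        assert reg == pytest.approx(cov, abs=1e-10)
        # invariant to weight rescaling and positive outcome rescaling
        scaled = rank_outcome(3.7 * h, wealth, 10.0 * w)
        assert ci_covariance(scaled).estimate == pytest.approx(cov, abs=1e-10)

    @pytest.mark.parametrize("n", [100, 1000, 10_000])
    def test_area_converges_to_covariance(self, n):
        rng = np.random.default_rng(n)
        h = rng.gamma(2.0, 1.0, size=n) + 0.01
        wealth = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        ranked = rank_outcome(h, wealth, w)
        gap = abs(ci_area(curve_points(ranked)).estimate
                  - ci_covariance(ranked).estimate)
        assert gap <= 2.0 / n


class TestDominance:
    def test_coincide_and_dominance(self):
        loe = ConcentrationCurve(p=np.array([0, 0.5, 1.0]),
                                 L=np.array([0, 0.5, 1.0]))
        below = ConcentrationCurve(p=np.array([0, 0.5, 1.0]),
                                   L=np.array([0, 0.3, 1.0]))
        assert dominance(loe, loe) == "coincide"
        assert dominance(loe, below) == "a_dominates"
        assert dominance(below, loe) == "b_dominates"

    def test_crossing_curves(self):
        a = ConcentrationCurve(p=np.array([0, 0.25, 0.75, 1.0]),
                               L=np.array([0, 0.30, 0.60, 1.0]))
        b = ConcentrationCurve(p=np.array([0, 0.25, 0.75, 1.0]),
                               L=np.array([0, 0.20, 0.70, 1.0]))
        assert dominance(a, b) == "cross"

    def test_interpolation_onto_union_grid(self):
        a = ConcentrationCurve(p=np.array([0, 0.5, 1.0]), L=np.array([0, 0.4, 1.0]))
        b = ConcentrationCurve(p=np.array([0, 0.25, 1.0]), L=np.array([0, 0.10, 1.0]))
        # on the union grid b touches a at p=0.5 and lies below at p=0.25
        assert dominance(a, b) == "a_dominates"
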