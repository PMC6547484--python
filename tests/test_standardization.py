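"""Covariate-standardized CI: prediction model, means-frozen predictions,
and the transformed-regressor standard error."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mchequity import (
    ci_adjusted,
    ci_covariance,
    fit_prediction_model,
    predict_at_means,
    rank_outcome,
)
from mchequity.concentration import _wls_slope, weighted_rank_variance

from conftest import random_weighted_dataset


def _simple_linear_data(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    wealth = rng.normal(size=n)
    control = rng.normal(size=n)  # orthogonal to wealth by construction
    h = 2.0 + 1.5 * wealth + 0.8 * control + rng.normal(0, 0.5, size=n)
    h = h - h.min() + 0.1  # keep outcomes non-negative
    w = rng.uniform(0.5, 2.0, size=n)
    return h, wealth, control, w


class TestPredictionModel:
    def test_identity_link_recovers_known_coefficients(self):
        h, wealth, control, w = _simple_linear_data()
        model = fit_prediction_model(
            h, pd.DataFrame({"wealth": wealth}),
            pd.DataFrame({"control": control}), w, link="identity")
        assert model.wealth_coef["wealth"] == pytest.approx(1.5, abs=0.05)
        assert model.control_coef["control"] == pytest.approx(0.8, abs=0.05)

    def test_zero_variance_control_rejected(self):
        h, wealth, control, w = _simple_linear_data(n=100)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_prediction_model(h, pd.DataFrame({"wealth": wealth}),
                                 pd.DataFrame({"flat": np.ones(100)}), w)

    def test_predict_at_means_hand_example(self):
        # 3 records, identity link: prediction = b0 + b_w * x + b_c * xbar_c
        h = np.array([1.0, 2.0, 3.0])
        wealth = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        control = pd.DataFrame({"c": [1.0, 0.0, 2.0]})
        w = np.ones(3)
        model = fit_prediction_model(h, wealth, control, w)
        pred = predict_at_means(model, wealth)
        expected = (model.intercept + model.wealth_coef["x"] * wealth["x"].to_numpy()
                    + model.control_coef["c"] * 1.0)
        np.testing.assert_allclose(pred, expected, atol=1e-10)

    def test_controls_at_their_means_equal_fitted_values(self):
        h, wealth, control, w = _simple_linear_data(n=500, seed=3)
        wn = w / w.sum()
        control_centered = control - np.sum(wn * control)
        model = fit_prediction_model(
            h, pd.DataFrame({"x": wealth}),
            pd.DataFrame({"c": control_centered}), w)
        pred = predict_at_means(model, pd.DataFrame({"x": wealth}))
        fitted = (model.intercept + model.wealth_coef["x"] * wealth
                  + model.control_coef["c"] * control_centered)
        # freezing a centered control at its (zero) mean removes exactly its
        # fitted contribution from each record
        np.testing.assert_allclose(pred - fitted,
                                   -model.control_coef["c"] * control_centered,
                                   atol=1e-8)

    def test_logit_link_prediction_bounded(self):
        rng = np.random.default_rng(5)
        n = 800
        wealth = rng.normal(size=n)
        ctrl = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + wealth)))).astype(float)
        model = fit_prediction_model(y, pd.DataFrame({"x": wealth}),
                                     pd.DataFrame({"c": ctrl}),
                                     np.ones(n), link="logit")
        pred = predict_at_means(model, pd.DataFrame({"x": wealth}))
        assert np.all((pred > 0) & (pred < 1))


class TestAdjustedCI:
    def test_zero_wealth_coefficient_gives_zero_adjusted_ci(self):
        rng = np.random.default_rng(7)
        n = 200
        ranked = rank_outcome(rng.gamma(2, 1, n) + 0.1, rng.normal(size=n),
                              np.ones(n))
        constant = np.full(n, 3.0)
        est = ci_adjusted(ranked, constant)
        assert est.estimate == pytest.approx(0.0, abs=1e-12)
        assert est.adjusted

    def test_no_controls_reduces_to_unadjusted(self):
        rng = np.random.default_rng(11)
        n = 600
        h = rng.gamma(2, 1, n) + 0.1
        wealth = rng.normal(size=n)
        w = rng.uniform(0.5, 2, n)
        ranked = rank_outcome(h, wealth, w)
        order = np.argsort(wealth, kind="stable")
        model = fit_prediction_model(h, pd.DataFrame({"x": wealth}),
                                     pd.DataFrame(index=range(n)), w)
        pred = predict_at_means(model, pd.DataFrame({"x": wealth[order]}))
        est = ci_adjusted(ranked, pred)
        unadj = ci_covariance(ranked).estimate
        # the fitted wealth line preserves the wealth-rank covariance pattern
        assert np.sign(est.estimate) == np.sign(unadj)
        # exact reduction: adjusted CI of the raw outcome itself
        assert ci_adjusted(ranked, ranked.h).estimate == pytest.approx(unadj, abs=1e-12)

    def test_confounding_through_residence_attenuates(self):
        # wealth affects the outcome only through an urban/rural channel:
        # adjusting for residence should pull the CI toward zero
        rng = np.random.default_rng(13)
        n = 4000
        urban = rng.random(n) < 0.4
        wealth = rng.normal(size=n) + 1.5 * urban
        h = 2.0 + 1.2 * urban + rng.normal(0, 0.4, size=n)
        h = h - h.min() + 0.1
        w = np.ones(n)
        ranked = rank_outcome(h, wealth, w)
        order = np.argsort(wealth, kind="stable")
        quint = pd.DataFrame({"q": pd.cut(wealth, 5, labels=False).astype(str)})
        model = fit_prediction_model(h, quint,
                                     pd.DataFrame({"urban": urban.astype(float)}), w)
        pred = predict_at_means(model, quint.iloc[order])
        adj = ci_adjusted(ranked, pred).estimate
        unadj = ci_covariance(ranked).estimate
        assert abs(adj) < 0.35 * abs(unadj)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_transformed_regressor_slope_equals_covariance_ci(self, seed):
        rng = np.random.default_rng(seed)
        h, wealth, w = random_weighted_dataset(rng, max_n=300)
        ranked = rank_outcome(h, wealth, w)
        mu = float(np.sum(ranked.w * ranked.h))
        var_r = weighted_rank_variance(ranked)
        rwealth = mu / (2 * var_r) * ranked.r
        slope, _ = _wls_slope(ranked.h, rwealth, ranked.w)
        assert slope == pytest.approx(ci_covariance(ranked).estimate, abs=1e-10)

    def test_standard_error_shrinks_with_sample_size(self):
        ses = []
        for n in (400, 1600, 6400):
            rng = np.random.default_rng(n)
            h = rng.gamma(2, 1, n) + 0.1
            wealth = rng.normal(size=n)
            ranked = rank_outcome(h, wealth, np.ones(n))
            ses.append(ci_adjusted(ranked, ranked.h).standard_error)
        # ~n^(-1/2): quadrupling n should roughly halve the SE
        assert ses[1] == pytest.approx(ses[0] / 2, rel=0.35)
        assert ses[2] == pytest.approx(ses[1] / 2, rel=0.35)

    def test_negative_adjusted_mean_is_surfaced(self):
        rng = np.random.default_rng(17)
        n = 50
        ranked = rank_outcome(rng.gamma(2, 1, n) + 0.1, rng.normal(size=n),
                              np.ones(n))
        with pytest.raises(ValueError, match="not positive"):
            ci_adjusted(ranked, np.full(n, -1.0))
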