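"""Solver correctness against independent oracles; CV selection behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from opiphen import (AdaptiveLassoFit, DataError, PenaltyConfig, SchemaError,
                     adaptive_weights, cv_grid_search, fit_ridge_logistic,
                     fit_weighted_lasso_logistic, penalized_objective,
                     predict_risk)
from opiphen.lasso import cv_fold_loss

NO_STD = PenaltyConfig(standardize=False)


def _logit_data(seed, n=150, p=6, beta=None, b0=0.2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.2, -0.8, 0.6][: min(3, p)]
    y = (rng.random(n) < 1 / (1 + np.exp(-(b0 + X @ beta)))).astype(float)
    if 0 < y.sum() < n:
        return X, y
    return _logit_data(seed + 1, n, p, beta, b0)


def _saga_objective(X, y, lam, weights=None):
    """Independent convex solver for NLL + lam*sum w|b|: saga on rescaled
    columns (the substitution X_j/w_j absorbs the weights)."""
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    Xs = X / w
    m = LogisticRegression(l1_ratio=1.0, solver="saga", C=1.0 / lam,
                           tol=1e-10, max_iter=500_000)
    m.fit(Xs, y)
    beta = m.coef_[0] / w
    return penalized_objective(X, y, float(m.intercept_[0]), beta, lam, w)


class TestRidge:
    def test_vanishing_penalty_matches_unpenalized_mle(self):
        X, y = _logit_data(0)
        b0, beta = fit_ridge_logistic(X, y, ridge_penalty=1e-8)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert b0 == pytest.approx(mle.params[0], abs=1e-4)
        assert np.allclose(beta, mle.params[1:], atol=1e-4)

    def test_huge_penalty_shrinks_to_intercept_only(self):
        X, y = _logit_data(1)
        b0, beta = fit_ridge_logistic(X, y, ridge_penalty=1e8)
        assert np.all(np.abs(beta) < 1e-5)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-3)

    def test_duplicated_columns_share_the_coefficient(self):
        X, y = _logit_data(2, p=3)
        Xdup = np.hstack([X, X[:, [0]]])
        _, beta = fit_ridge_logistic(Xdup, y, ridge_penalty=2.0)
        assert beta[0] == pytest.approx(beta[3], abs=1e-6)


class TestAdaptiveWeights:
    def test_inverse_power_formula(self):
        assert np.allclose(adaptive_weights([2.0, 0.5], gamma=1.0), [0.5, 2.0])

    def test_gamma_zero_gives_unit_weights(self):
        assert np.allclose(adaptive_weights([2.0, 0.5, 0.0], gamma=0.0), 1.0)

    def test_zero_coefficient_clamped_at_floor(self):
        w = adaptive_weights([0.0], gamma=2.0, floor=1e-6)
        assert w[0] == pytest.approx(1e12)


class TestWeightedLasso:
    def test_zero_lambda_matches_unpenalized_mle(self):
        X, y = _logit_data(3)
        fit = fit_weighted_lasso_logistic(X, y, lam=0.0, config=NO_STD)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.intercept == pytest.approx(mle.params[0], abs=1e-5)
        assert np.allclose(fit.coefs, mle.params[1:], atol=1e-5)

    def test_large_lambda_empties_the_model(self):
        X, y = _logit_data(4)
        fit = fit_weighted_lasso_logistic(X, y, lam=1e5, config=NO_STD)
        assert fit.retained == []
        assert fit.intercept == pytest.approx(
            np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_reported_zeros_are_exact(self):
        X, y = _logit_data(5, n=120, p=10)
        fit = fit_weighted_lasso_logistic(X, y, lam=15.0, config=NO_STD)
        zero = fit.coefs[fit.coefs == 0.0]
        assert len(zero) > 0
        assert all(v == 0.0 for v in zero)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_objective_matches_convex_solver(self, seed):
        X, y = _logit_data(seed, n=180, p=8)
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.3, 3.0, X.shape[1])
        lam = rng.uniform(1.0, 8.0)
        fit = fit_weighted_lasso_logistic(X, y, lam, weights, NO_STD)
        mine = penalized_objective(X, y, fit.intercept, fit.coefs, lam, weights)
        oracle = _saga_objective(X, y, lam, weights)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_unit_weights_reduce_to_plain_lasso(self):
        X, y = _logit_data(20, n=150, p=6)
        lam = 4.0
        fit = fit_weighted_lasso_logistic(X, y, lam, None, NO_STD)
        mine = penalized_objective(X, y, fit.intercept, fit.coefs, lam)
        assert mine == pytest.approx(_saga_objective(X, y, lam), rel=1e-6)

    def test_standardized_fit_reports_original_scale(self):
        X, y = _logit_data(6)
        X[:, 0] *= 100.0
        fit = fit_weighted_lasso_logistic(X, y, lam=0.0,
                                          config=PenaltyConfig(standardize=True))
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coefs, mle.params[1:], atol=1e-4)


class TestCV:
    def test_fold_loss_formula(self):
        assert cv_fold_loss([1, 0], [0.8, 0.1]) == pytest.approx(0.05)

    def test_single_class_minority_raises(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.r_[np.ones(4), np.zeros(36)]
        with pytest.raises(DataError, match="fold"):
            cv_grid_search(X, y, PenaltyConfig(n_folds=8))

    def test_pure_noise_selects_a_near_empty_model(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(300, 25))
        y = (rng.random(300) < 0.3).astype(float)
        fit = cv_grid_search(X, y, PenaltyConfig(fold_seed=0, n_lambda=20))
        assert len(fit.retained) <= 3

    def test_strong_predictor_is_retained(self):
        for seed in (1, 2, 3):
            beta = np.zeros(10)
            beta[0] = 2.0
            X, y = _logit_data(seed, n=400, p=10, beta=beta, b0=-0.5)
            Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(10)])
            fit = cv_grid_search(Xdf, y, PenaltyConfig(fold_seed=seed,
                                                       n_lambda=20))
            assert "x0" in fit.retained

    def test_tie_break_prefers_sparser_model(self):
        # a near-constant loss surface must resolve to the largest lambda
        X, y = _logit_data(9, n=100, p=4)
        fit = cv_grid_search(X, y, PenaltyConfig(
            gamma_grid=(1.0,), lambda_grid=(0.5, 0.5000000001), n_folds=4))
        assert fit.lam == pytest.approx(0.5000000001)


class TestPredict:
    def test_all_zero_row_gives_logistic_intercept(self):
        fit = AdaptiveLassoFit(0.4, pd.Series({"a": 1.0, "b": -2.0}), None,
                               1.0, 0.1, 3, True)
        p = predict_risk(fit, pd.DataFrame({"a": [0.0], "b": [0.0]}))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-0.4)))

    def test_zero_linear_predictor_is_half(self):
        fit = AdaptiveLassoFit(0.0, pd.Series({"a": 1.0}), None, 1.0, 0.1, 3,
                               True)
        assert predict_risk(fit, pd.DataFrame({"a": [0.0]}))[0] == 0.5

    def test_monotone_in_positive_coefficient(self):
        fit = AdaptiveLassoFit(-0.3, pd.Series({"a": 0.8, "b": -0.2}), None,
                               1.0, 0.1, 3, True)
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"a": rng.normal(size=50),
                             "b": rng.normal(size=50)})
        bumped = rows.assign(a=rows["a"] + 1.0)
        assert (predict_risk(fit, bumped) >= predict_risk(fit, rows)).all()

    def test_missing_column_is_a_schema_error(self):
        fit = AdaptiveLassoFit(0.0, pd.Series({"a": 1.0, "b": 1.0}), None,
                               1.0, 0.1, 3, True)
        with pytest.raises(SchemaError, match="b"):
            predict_risk(fit, pd.DataFrame({"a": [1.0]}))

    def test_model_json_round_trip(self, tmp_path):
        X, y = _logit_data(30, n=120, p=5)
        Xdf = pd.DataFrame(X, columns=list("abcde"))
        fit = fit_weighted_lasso_logistic(Xdf, y, lam=2.0)
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = AdaptiveLassoFit.from_json(path)
        assert back.intercept == pytest.approx(fit.intercept)
        pd.testing.assert_series_equal(back.coefs, fit.coefs)
        assert np.allclose(predict_risk(back, Xdf), predict_risk(fit, Xdf))
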