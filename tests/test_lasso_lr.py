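"""Penalized logistic solver: KKT optimality, path endpoints, CV selection."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from breathvoc.lasso_lr import (
    ConvergenceError,
    DesignMatrix,
    cv_select_lambda,
    fit_lasso_lr,
    kkt_residual,
    lambda_max,
    odds_ratios,
    predict_prob,
    standardize,
)


def _logistic_data(rng, n=80, p=5, beta=None, intercept=0.3):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.0, -0.5, 0.25][: min(3, p)]
    prob = 1 / (1 + np.exp(-(intercept + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if len(np.unique(y)) < 2:  # pragma: no cover - improbable at these sizes
        y[0] = 1 - y[0]
    return X, y


def _dm(X):
    return DesignMatrix(X, [f"v{i}" for i in range(X.shape[1])])


class TestStandardize:
    def test_two_point_column(self):
        dm = standardize(_dm(np.array([[0.0], [2.0]])))
        np.testing.assert_allclose(dm.X[:, 0], [-1, 1])
        assert dm.standardization["v0"] == (1.0, 1.0)

    def test_constant_column_dropped(self):
        dm = standardize(_dm(np.array([[1.0, 5.0], [2.0, 5.0]])))
        assert dm.variable_names == ["v0"]
        assert dm.dropped == ["v1"]

    def test_back_transform_preserves_predictions(self, rng):
        X, y = _logistic_data(rng)
        dms = standardize(_dm(X))
        model = fit_lasso_lr(dms, y, 0.02)
        # original-scale coefficients on raw X must equal standardized-scale
        # coefficients on standardized X
        p_raw = predict_prob(model, X)
        eta_std = model.intercept_standardized + dms.X @ model.beta_standardized
        p_std = 1 / (1 + np.exp(-eta_std))
        np.testing.assert_allclose(p_raw, p_std, atol=1e-10)


class TestLambdaMax:
    def test_hand_value_single_feature(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        # standardized x equals x here; |x^T (y - 0.5)| / 4 = 0.5
        assert lambda_max(X, y) == pytest.approx(0.5)

    def test_fit_above_lambda_max_is_intercept_only(self, rng):
        X, y = _logistic_data(rng)
        lmax = lambda_max(X, y)
        model = fit_lasso_lr(standardize(_dm(X)), y, 1.01 * lmax)
        assert model.selected == []
        ybar = y.mean()
        assert model.intercept_standardized == pytest.approx(
            np.log(ybar / (1 - ybar))
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            lambda_max(rng.normal(size=(10, 2)), np.ones(10))


class TestFitLassoLr:
    def test_unpenalized_matches_mle_oracle(self, rng):
        for _ in range(20):
            X, y = _logistic_data(rng, n=50, p=3)
            model = fit_lasso_lr(standardize(_dm(X)), y, 0.0, tol=1e-8)
            oracle = LogisticRegression(
                C=np.inf, tol=1e-12, max_iter=20000
            ).fit(X, y)
            assert np.abs(model.beta - oracle.coef_[0]).max() < 1e-4
            assert abs(model.intercept - oracle.intercept_[0]) < 1e-4

    def test_kkt_residual_within_tol_across_lambdas(self, rng):
        X, y = _logistic_data(rng, n=60, p=8)
        dms = standardize(_dm(X))
        lmax = lambda_max(X, y)
        for lam in [0.8 * lmax, 0.3 * lmax, 0.05 * lmax, 0.005 * lmax]:
            model = fit_lasso_lr(dms, y, lam, tol=1e-7)
            assert kkt_residual(model, dms, y) <= 1e-7

    def test_negative_lambda_rejected(self, rng):
        X, y = _logistic_data(rng)
        with pytest.raises(ValueError):
            fit_lasso_lr(standardize(_dm(X)), y, -0.1)

    def test_non_convergence_within_max_iter_raises(self, rng):
        X, y = _logistic_data(rng, n=60, p=8)
        with pytest.raises(ConvergenceError, match="KKT"):
            fit_lasso_lr(standardize(_dm(X)), y, 0.0, tol=1e-12, max_iter=1)

    def test_prediction_invariant_to_column_rescaling(self, rng):
        X, y = _logistic_data(rng, n=70, p=4)
        scales = np.array([1.0, 100.0, 0.01, 7.3])
        m1 = fit_lasso_lr(standardize(_dm(X)), y, 0.03)
        m2 = fit_lasso_lr(standardize(_dm(X * scales)), y, 0.03)
        np.testing.assert_allclose(
            predict_prob(m1, X), predict_prob(m2, X * scales), atol=1e-6
        )

    def test_warm_path_equals_cold_fits(self, rng):
        from breathvoc.lasso_lr import _fit_path_standardized, lambda_grid

        X, y = _logistic_data(rng, n=60, p=6)
        dms = standardize(_dm(X))
        grid = lambda_grid(X, y, n_lambda=8)
        b0_path, beta_path, _, conv = _fit_path_standardized(
            dms.X, y, grid, 1e-8, 100_000
        )
        assert conv.all()
        for i, lam in enumerate(grid):
            cold = fit_lasso_lr(dms, y, float(lam), tol=1e-8)
            assert np.abs(beta_path[i] - cold.beta_standardized).max() < 1e-6


class TestPredictAndOddsRatios:
    def test_all_zero_model_gives_half(self):
        X = np.array([[1.0], [2.0], [3.0], [0.0]])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        dms = standardize(_dm(X))
        model = fit_lasso_lr(dms, y, 10.0)  # way above lambda_max
        model.intercept = 0.0  # closed-form check of the link
        np.testing.assert_allclose(predict_prob(model, X), 0.5)

    def test_closed_form_single_variable(self):
        from breathvoc.lasso_lr import LassoModel

        model = LassoModel(
            lambda_=0.0, intercept=0.0, beta=np.array([1.0]),
            beta_standardized=np.array([1.0]), intercept_standardized=0.0,
            variable_names=["x"], standardization={"x": (0.0, 1.0)},
        )
        assert predict_prob(model, np.array([[0.0]]))[0] == pytest.approx(0.5)
        assert predict_prob(model, np.array([[np.log(3)]]))[0] == pytest.approx(0.75)

    def test_odds_ratio_closed_form_and_selection(self, rng):
        from breathvoc.lasso_lr import LassoModel

        model = LassoModel(
            lambda_=0.1, intercept=0.0, beta=np.array([np.log(2), 0.0]),
            beta_standardized=np.array([0.7, 0.0]), intercept_standardized=0.0,
            variable_names=["a", "b"],
            standardization={"a": (0, 1), "b": (0, 1)},
        )
        ors = odds_ratios(model)
        assert ors == {"a": pytest.approx(2.0)}

    def test_odds_ratio_equivariance_at_lambda_zero(self, rng):
        X, y = _logistic_data(rng, n=100, p=3)
        model = fit_lasso_lr(standardize(_dm(X)), y, 0.0, tol=1e-9)
        oracle = LogisticRegression(C=np.inf, tol=1e-12, max_iter=20000).fit(X, y)
        for j, name in enumerate(model.variable_names):
            assert odds_ratios(model)[name] == pytest.approx(
                np.exp(oracle.coef_[0][j]), rel=1e-5
            )

    def test_variable_mismatch_rejected(self, rng):
        X, y = _logistic_data(rng)
        model = fit_lasso_lr(standardize(_dm(X)), y, 0.05)
        with pytest.raises(ValueError):
            predict_prob(model, X[:, :2])


class TestCvSelectLambda:
    def test_determinism(self, rng):
        X, y = _logistic_data(rng, n=60, p=10)
        dm = _dm(X)
        r1 = cv_select_lambda(dm, y, seed=5, n_lambda=20)
        r2 = cv_select_lambda(dm, y, seed=5, n_lambda=20)
        assert r1.chosen_lambda == r2.chosen_lambda
        for f1, f2 in zip(r1.folds, r2.folds):
            np.testing.assert_array_equal(f1, f2)

    def test_folds_partition_and_stratify(self, rng):
        X, y = _logistic_data(rng, n=55, p=4)
        res = cv_select_lambda(_dm(X), y, k=5, n_lambda=10, seed=0)
        all_idx = np.sort(np.concatenate(res.folds))
        np.testing.assert_array_equal(all_idx, np.arange(55))
        for fold in res.folds:
            assert len(np.unique(y[fold])) == 2

    def test_pure_noise_selects_sparse_models(self):
        n_selected = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 30))
            y = np.r_[np.ones(20), np.zeros(80)]
            y = rng.permutation(y)
            dm = _dm(X)
            res = cv_select_lambda(dm, y, seed=seed, n_lambda=30)
            model = fit_lasso_lr(standardize(dm), y, res.chosen_lambda)
            n_selected.append(len(model.selected))
        assert np.median(n_selected) <= 2

    def test_planted_signal_recovered(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            beta = np.zeros(20)
            beta[:3] = 1.5
            X, y = _logistic_data(rng, n=200, p=20, beta=beta, intercept=0.0)
            dm = _dm(X)
            res = cv_select_lambda(dm, y, seed=seed, n_lambda=30)
            model = fit_lasso_lr(standardize(dm), y, res.chosen_lambda)
            if {"v0", "v1", "v2"} <= set(model.selected):
                hits += 1
        assert hits >= 9
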