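"""Ridge closed form vs oracles, network training, evaluation protocol."""

import numpy as np
import pytest

from ftirbind.regression import (
    MLPRegressor,
    RidgeRegressor,
    evaluate,
    fit_mlp,
    fit_ridge,
    r2_score,
)


def _toy_data(seed=0, n=12, d=2, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X = (X - X.mean(0)) / X.std(0)
    w = np.array([2.0, -1.0])[:d]
    y = X @ w + 5.0 + noise * rng.normal(size=n)
    return X, y


def _brute_force_ridge(X, y, alpha):
    """Independent oracle: solve the penalized normal equations on the
    intercept-augmented system, penalizing only the non-intercept block."""
    n, d = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    penalty = np.diag([0.0] + [alpha] * d)
    theta = np.linalg.solve(A.T @ A + penalty, A.T @ y)
    return theta[0], theta[1:]


class TestFitRidge:
    def test_perfect_line_alpha_zero(self):
        x = np.linspace(-1, 1, 7)[:, None]
        model = fit_ridge(x, x.ravel(), alpha=0.0)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_infinite_penalty_limit(self):
        X, y = _toy_data(noise=0.1)
        model = fit_ridge(X, y, alpha=1e9)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-6)
        assert model.intercept == pytest.approx(y.mean(), abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 10.0])
    def test_matches_brute_force_normal_equations(self, alpha):
        X, y = _toy_data(seed=3, n=5, noise=0.3)
        model = fit_ridge(X, y, alpha=alpha)
        intercept, coef = _brute_force_ridge(X, y, alpha)
        np.testing.assert_allclose(model.coefficients, coef, atol=1e-8)
        assert model.intercept == pytest.approx(intercept, abs=1e-8)

    def test_matches_sklearn(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = _toy_data(seed=5, n=20, noise=0.5)
        model = fit_ridge(X, y, alpha=1.0)
        ref = sklearn_linear.Ridge(alpha=1.0).fit(X, y)
        np.testing.assert_allclose(model.coefficients, ref.coef_, atol=1e-8)
        assert model.intercept == pytest.approx(ref.intercept_, abs=1e-8)

    def test_alpha_zero_equals_ols(self):
        X, y = _toy_data(seed=7, n=15, noise=0.2)
        model = fit_ridge(X, y, alpha=0.0)
        A = np.hstack([np.ones((len(y), 1)), X])
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.coefficients, theta[1:], atol=1e-8)

    def test_collinear_alpha_zero_raises(self):
        x = np.linspace(0, 1, 8)
        X = np.c_[x, 2 * x]  # perfectly collinear
        with pytest.raises(np.linalg.LinAlgError):
            fit_ridge(X, x, alpha=0.0)

    def test_training_residuals_sum_to_zero(self):
        X, y = _toy_data(seed=11, n=25, noise=1.0)
        model = fit_ridge(X, y, alpha=1.0)
        resid = model.predict(X) - y
        assert abs(resid.sum()) < 1e-8

    def test_row_order_invariance(self):
        X, y = _toy_data(seed=13, n=20, noise=0.5)
        perm = np.random.default_rng(0).permutation(len(y))
        a = fit_ridge(X, y, alpha=1.0)
        b = fit_ridge(X[perm], y[perm], alpha=1.0)
        np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-9)


class TestFitMLP:
    def test_zero_epochs_returns_seeded_init(self):
        X, y = _toy_data()
        model = fit_mlp(X, y, seed=42, epochs=0)
        rng = np.random.default_rng(42)
        np.testing.assert_array_equal(model.W1, rng.uniform(-0.5, 0.5, (2, 5)))
        np.testing.assert_array_equal(model.b1, rng.uniform(-0.5, 0.5, 5))
        np.testing.assert_array_equal(model.W2, rng.uniform(-0.5, 0.5, (5, 1)))
        np.testing.assert_array_equal(model.b2, rng.uniform(-0.5, 0.5, 1))

    def test_same_seed_identical_weights(self):
        X, y = _toy_data()
        a = fit_mlp(X, y, seed=1, epochs=500)
        b = fit_mlp(X, y, seed=1, epochs=500)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)
        np.testing.assert_array_equal(a.b1, b.b1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_learns_noiseless_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 2.0 * X[:, 0] + X[:, 1]
        model = fit_mlp(X, y, seed=0, epochs=5000, learning_rate=0.05)
        mse = float(np.mean((model.predict(X) - y) ** 2))
        assert mse < 1e-2

    def test_loss_trace_nonincreasing_after_warmup(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 2.0 * X[:, 0] + X[:, 1]
        model = fit_mlp(X, y, seed=0, epochs=2000, learning_rate=0.05)
        warmup = len(model.loss_history) // 10
        tail = model.loss_history[warmup:]
        assert np.all(np.diff(tail) <= 1e-10)

    def test_divergence_reported_not_clipped(self):
        X, y = _toy_data()
        with pytest.raises(FloatingPointError, match="learning_rate"):
            fit_mlp(X, 1e3 * y, seed=0, epochs=5000, learning_rate=50.0)


class TestEvaluate:
    def test_perfect_linear_fit(self):
        X, y = _toy_data(seed=2, n=20)
        report = evaluate(RidgeRegressor(alpha=0.0), X, y, split_seed=0)
        assert report.r2 == pytest.approx(1.0, abs=1e-9)
        assert report.mse == pytest.approx(0.0, abs=1e-9)

    def test_constant_model_nonpositive_r2(self):
        class ConstantModel:
            def fit(self, X, y):
                self.value = y.mean()
                return self

            def predict(self, X):
                return np.full(len(X), self.value)

            def clone(self):
                return ConstantModel()

        X, y = _toy_data(seed=4, n=20, noise=0.5)
        report = evaluate(ConstantModel(), X, y, split_seed=0)
        assert report.r2 <= 0.0

    def test_five_folds_partition_25_rows(self):
        X, y = _toy_data(seed=6, n=25, noise=0.1)
        report = evaluate(RidgeRegressor(alpha=1.0), X, y, split_seed=3)
        counts = np.bincount(report.fold_assignments)[1:]
        assert list(counts) == [5, 5, 5, 5, 5]

    def test_fold_assignment_reproducible(self):
        X, y = _toy_data(seed=6, n=25, noise=0.1)
        a = evaluate(RidgeRegressor(alpha=1.0), X, y, split_seed=3)
        b = evaluate(RidgeRegressor(alpha=1.0), X, y, split_seed=3)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.test_indices, b.test_indices)

    def test_too_few_samples_rejected(self):
        X, y = _toy_data(n=4)
        with pytest.raises(ValueError, match="5-fold"):
            evaluate(RidgeRegressor(), X, y, split_seed=0)


def test_r2_score_definition():
    y = np.array([1.0, 2.0, 3.0])
    assert r2_score(y, y) == 1.0
    assert r2_score(y, np.full(3, y.mean())) == 0.0
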