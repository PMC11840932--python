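"""Distance regressors and the validation protocol.

Two predictors share one fit/predict interface:

* :class:`RidgeRegressor` — closed-form L2-penalized least squares
  (penalty strength α, default 1.0; the intercept is not penalized),
  solved exactly from the penalized normal equations.
* :class:`MLPRegressor` — a fixed 2-5-1 feed-forward network with ReLU
  hidden units trained by full-batch gradient descent on squared error;
  deterministic given the seed.

``evaluate`` applies the study's protocol: a seeded 80/20 train/test
split plus 5-fold cross-validation (seeded shuffle, contiguous blocks),
reporting MSE and R² with residuals and fold assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

__all__ = [
    "RidgeModel",
    "MLPModel",
    "EvalReport",
    "RidgeRegressor",
    "MLPRegressor",
    "fit_ridge",
    "fit_mlp",
    "evaluate",
    "r2_score",
]


@dataclass(frozen=True)
class RidgeModel:
    coefficients: np.ndarray  # Å per normalized feature unit
    intercept: float  # Å
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


@dataclass
class MLPModel:
    """Weights of the fixed 2-5-1 ReLU network.

    The trainer standardizes the target internally; ``y_mean``/``y_std``
    undo that scaling at prediction time.
    """

    W1: np.ndarray  # (n_features, 5)
    b1: np.ndarray  # (5,)
    W2: np.ndarray  # (5, 1)
    b2: np.ndarray  # (1,)
    seed: int
    epochs: int
    learning_rate: float
    y_mean: float = 0.0
    y_std: float = 1.0
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        hidden = np.maximum(X @ self.W1 + self.b1, 0.0)
        out = (hidden @ self.W2 + self.b2).ravel()
        return out * self.y_std + self.y_mean


def fit_ridge(features: np.ndarray, targets: np.ndarray, alpha: float = 1.0) -> RidgeModel:
    """Exact closed-form ridge solve with an unpenalized intercept.

    Centering X and y removes the intercept from the penalized system;
    the coefficients then solve (Xc'Xc + αI) w = Xc'y.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if X.shape[0] != y.size:
        raise ValueError("features and targets disagree in sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    gram = Xc.T @ Xc + alpha * np.eye(X.shape[1])
    try:
        coef = np.linalg.solve(gram, Xc.T @ yc)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular penalized system (alpha={alpha}); features collinear"
        ) from exc
    if alpha == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError("singular system at alpha=0 with collinear features")
    intercept = y_mean - x_mean @ coef
    return RidgeModel(coefficients=coef, intercept=float(intercept), alpha=alpha)


def fit_mlp(
    features: np.ndarray,
    targets: np.ndarray,
    seed: int,
    epochs: int = 20000,
    learning_rate: float = 0.05,
    n_hidden: int = 5,
) -> MLPModel:
    """Train the 2-5-1 ReLU network by full-batch gradient descent.

    Weights initialize uniformly in [-0.5, 0.5] from the seed; with
    ``epochs=0`` the returned weights are exactly that initialization.
    A non-finite training loss (learning rate too large) raises
    ``FloatingPointError`` instead of being clipped.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching targets")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if epochs < 0 or learning_rate <= 0:
        raise ValueError("epochs must be >= 0 and learning_rate > 0")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (d, n_hidden))
    b1 = rng.uniform(-0.5, 0.5, n_hidden)
    W2 = rng.uniform(-0.5, 0.5, (n_hidden, 1))
    b2 = rng.uniform(-0.5, 0.5, 1)

    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std < 1e-12:
        y_std = 1.0
    yz = (y - y_mean) / y_std

    losses = np.empty(epochs)
    for epoch in range(epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            Z1 = X @ W1 + b1
            A1 = np.maximum(Z1, 0.0)
            out = (A1 @ W2 + b2).ravel()
            err = out - yz
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss became non-finite at epoch {epoch}; "
                f"reduce learning_rate (current {learning_rate})"
            )
        losses[epoch] = loss
        grad_out = (2.0 / n) * err[:, None]
        gW2 = A1.T @ grad_out
        gb2 = grad_out.sum(axis=0)
        gZ1 = (grad_out @ W2.T) * (Z1 > 0)
        gW1 = X.T @ gZ1
        gb1 = gZ1.sum(axis=0)
        W1 -= learning_rate * gW1
        b1 -= learning_rate * gb1
        W2 -= learning_rate * gW2
        b2 -= learning_rate * gb2

    return MLPModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        seed=seed, epochs=epochs, learning_rate=learning_rate,
        y_mean=y_mean, y_std=y_std, loss_history=losses,
    )


class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Regressor": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class RidgeRegressor:
    """Unfitted-estimator wrapper around :func:`fit_ridge`."""

    alpha: float = 1.0
    model: RidgeModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeRegressor":
        self.model = fit_ridge(X, y, self.alpha)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("regressor is not fitted")
        return self.model.predict(X)

    def clone(self) -> "RidgeRegressor":
        return RidgeRegressor(alpha=self.alpha)

    @property
    def coefficients(self) -> np.ndarray | None:
        return None if self.model is None else self.model.coefficients


@dataclass
class MLPRegressor:
    """Unfitted-estimator wrapper around :func:`fit_mlp`."""

    seed: int = 0
    epochs: int = 20000
    learning_rate: float = 0.05
    model: MLPModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        self.model = fit_mlp(X, y, self.seed, self.epochs, self.learning_rate)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("regressor is not fitted")
        return self.model.predict(X)

    def clone(self) -> "MLPRegressor":
        return MLPRegressor(seed=self.seed, epochs=self.epochs,
                            learning_rate=self.learning_rate)

    @property
    def coefficients(self) -> np.ndarray | None:
        # feature relevance proxy: L2 norm of each input's hidden weights
        return None if self.model is None else np.linalg.norm(self.model.W1, axis=1)


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        # no variance in y_true (e.g. single-sample fold): R² undefined
        return 1.0 if ss_res == 0 else float("nan")
    return 1.0 - ss_res / ss_tot


@dataclass
class EvalReport:
    """Held-out metrics from the 80/20 split plus 5-fold CV spread."""

    mse: float  # Å², held-out 20% split
    r2: float
    residuals: np.ndarray  # predicted - actual on test rows, Å
    residual_mean: float
    fold_assignments: np.ndarray  # 1..n_folds per sample, original order
    cv_mse_mean: float
    cv_mse_sd: float
    cv_r2_mean: float
    cv_r2_sd: float
    coefficients: np.ndarray | None
    test_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("MSE must be >= 0")
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("R² cannot exceed 1")


def evaluate(
    model: Regressor,
    features: np.ndarray,
    targets: np.ndarray,
    split_seed: int,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> EvalReport:
    """80/20 held-out evaluation plus seeded k-fold cross-validation.

    Folds are contiguous blocks of a seeded shuffle, so the partition is
    reproducible from ``split_seed`` alone.  The model object is cloned
    (via ``clone()``) for every refit.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    n = y.size
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV, got {n}")

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(n)

    # 80/20 split: last test_fraction of the shuffled order is held out
    n_test = max(1, int(round(test_fraction * n)))
    test_idx = order[:n_test]
    train_idx = order[n_test:]
    fitted = model.clone().fit(X[train_idx], y[train_idx])
    pred = fitted.predict(X[test_idx])
    residuals = pred - y[test_idx]
    mse = float(np.mean(residuals**2))
    r2 = r2_score(y[test_idx], pred)

    # k-fold CV on a fresh shuffle from the same seed stream
    cv_order = rng.permutation(n)
    folds = np.array_split(cv_order, n_folds)
    fold_assignments = np.empty(n, dtype=int)
    cv_mse = []
    cv_r2 = []
    for f, fold in enumerate(folds, start=1):
        fold_assignments[fold] = f
        tr = np.setdiff1d(cv_order, fold)
        m = model.clone().fit(X[tr], y[tr])
        p = m.predict(X[fold])
        cv_mse.append(float(np.mean((p - y[fold]) ** 2)))
        cv_r2.append(r2_score(y[fold], p))

    coef = getattr(fitted, "coefficients", None)
    return EvalReport(
        mse=mse,
        r2=r2,
        residuals=residuals,
        residual_mean=float(residuals.mean()),
        fold_assignments=fold_assignments,
        cv_mse_mean=float(np.mean(cv_mse)),
        cv_mse_sd=float(np.std(cv_mse)),
        # single-sample folds have undefined R²; aggregate over the rest
        cv_r2_mean=float(np.nanmean(cv_r2)) if not np.all(np.isnan(cv_r2)) else float("nan"),
        cv_r2_sd=float(np.nanstd(cv_r2)) if not np.all(np.isnan(cv_r2)) else float("nan"),
        coefficients=None if coef is None else np.asarray(coef, dtype=float),
        test_indices=test_idx,
    )
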