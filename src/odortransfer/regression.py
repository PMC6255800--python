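"""Multi-output elastic-net linear regression.

Every linear map in the framework (semantics-to-semantics ``S``,
ratings-to-ratings ``R``, chemistry-to-ratings ``C``) is estimated by
minimizing, independently per output column,

    sum_i ||Y_i - A X_i||_2^2  +  lambda1 ||A||_1  +  lambda2 ||A||_2^2,

with the regularization strengths (lambda1, lambda2) shared across outputs
and chosen by inner k-fold cross-validation on pooled held-out squared error
(10 folds by default).  The intercept is fit by column-centering and never
penalized.

The solver delegates to scikit-learn: ordinary least squares when both
penalties are zero, closed-form ridge when only the L2 penalty is active, and
coordinate-descent elastic net otherwise.  The penalty parametrization above
(raw sums of squares, not per-sample means) is mapped onto scikit-learn's
``alpha``/``l1_ratio`` internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetConfig",
    "LinearMap",
    "ElasticNetMap",
    "fit_elastic_net",
    "predict_linear",
    "penalized_objective",
]

_DEFAULT_GRID = (0.0,) + tuple(np.logspace(-3.0, 1.0, 7))


@dataclass(frozen=True)
class ElasticNetConfig:
    """Grids and cross-validation settings for the elastic-net fits."""

    lambda1_grid: tuple[float, ...] = _DEFAULT_GRID
    lambda2_grid: tuple[float, ...] = _DEFAULT_GRID
    inner_folds: int = 10
    seed: int = 0
    fit_intercept: bool = True
    standardize: bool = False

    def __post_init__(self) -> None:
        if not self.lambda1_grid or not self.lambda2_grid:
            raise ValueError("lambda grids must be non-empty")
        if any(l < 0 for l in self.lambda1_grid + self.lambda2_grid):
            raise ValueError("lambda values must be non-negative")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        object.__setattr__(self, "lambda1_grid", tuple(float(x) for x in self.lambda1_grid))
        object.__setattr__(self, "lambda2_grid", tuple(float(x) for x in self.lambda2_grid))


@dataclass(frozen=True)
class LinearMap:
    """A fitted affine map ``y = W x + b`` with fit metadata."""

    weights: np.ndarray  # [n_outputs x n_inputs]
    offset: np.ndarray  # [n_outputs]
    chosen_lambdas: tuple[float, float] = (0.0, 0.0)
    fit_diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        offset = np.asarray(self.offset, dtype=float).ravel()
        if offset.shape[0] != weights.shape[0]:
            raise ValueError("offset length must equal number of outputs")
        if not (np.all(np.isfinite(weights)) and np.all(np.isfinite(offset))):
            raise ValueError("LinearMap entries must be finite")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "offset", offset)

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_linear(self, X)


def predict_linear(linmap: LinearMap, X: np.ndarray) -> np.ndarray:
    """Apply ``X @ W.T + b`` row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != linmap.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} columns but the map expects {linmap.n_inputs}"
        )
    out = X @ linmap.weights.T + linmap.offset
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction")
    return out


def penalized_objective(
    weights: np.ndarray,
    offset: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    """The penalized squared-error objective being minimized (offset unpenalized)."""
    W = np.atleast_2d(weights)
    resid = Y - (X @ W.T + np.asarray(offset).ravel())
    return float(
        np.sum(resid**2) + lambda1 * np.sum(np.abs(W)) + lambda2 * np.sum(W**2)
    )


def _solve(
    X: np.ndarray,
    Y: np.ndarray,
    lambda1: float,
    lambda2: float,
    fit_intercept: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ||Y-XW'||^2 + lambda1|W| + lambda2 W^2 for one penalty pair."""
    n, p = X.shape
    q = Y.shape[1]
    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc, Yc = X - x_mean, Y - y_mean
    else:
        x_mean = np.zeros(p)
        y_mean = np.zeros(q)
        Xc, Yc = X, Y

    if lambda1 == 0.0 and lambda2 == 0.0:
        W = np.linalg.lstsq(Xc, Yc, rcond=None)[0].T  # min-norm OLS
    elif lambda1 == 0.0:
        # ridge: closed-form solution of ||y-Xw||^2 + lambda2 ||w||^2
        model = Ridge(alpha=lambda2, fit_intercept=False, solver="cholesky")
        model.fit(Xc, Yc)
        W = np.atleast_2d(model.coef_)
    else:
        # scikit-learn objective: (1/2n)||y-Xw||^2 + a*l1|w| + (a(1-l1)/2)||w||^2
        alpha = lambda1 / (2.0 * n) + lambda2 / n
        l1_ratio = (lambda1 / (2.0 * n)) / alpha
        model = ElasticNet(
            alpha=alpha,
            l1_ratio=l1_ratio,
            fit_intercept=False,
            max_iter=20_000,
            tol=1e-6,
        )
        with warnings.catch_warnings():
            # near-zero penalties legitimately stop on max_iter; the
            # residual duality gap is far below our comparison tolerances
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xc, Yc)
        W = np.atleast_2d(model.coef_)
    offset = y_mean - W @ x_mean
    return W, offset


class ElasticNetMap(BaseEstimator, RegressorMixin):
    """Multi-output elastic net with internal (lambda1, lambda2) selection.

    scikit-learn-style estimator: ``fit(X, Y)`` / ``predict(X)``; fitted
    attributes carry a trailing underscore.  The two penalty strengths are
    selected jointly for all outputs by inner k-fold cross-validation
    minimizing pooled held-out squared error; exact ties are broken toward
    the larger total penalty.

    Parameters
    ----------
    lambda1_grid, lambda2_grid : sequence of float
        Candidate L1 / L2 strengths (raw-objective parametrization).
    inner_folds : int
        Folds of the inner selection loop; silently reduced (with a logged
        warning) when there are fewer samples than folds.
    seed : int
        Seeds the fold assignment; fits are deterministic given the seed and
        invariant to training-row order up to fold assignment.
    fit_intercept : bool
        Fit an unpenalized offset via column-centering.
    standardize : bool
        Z-score the columns of X before fitting (weights are reported on the
        original scale).  Off by default: ratings and embedding columns are
        already commensurate within a matrix.
    """

    def __init__(
        self,
        lambda1_grid: Sequence[float] = _DEFAULT_GRID,
        lambda2_grid: Sequence[float] = _DEFAULT_GRID,
        inner_folds: int = 10,
        seed: int = 0,
        fit_intercept: bool = True,
        standardize: bool = False,
    ):
        self.lambda1_grid = lambda1_grid
        self.lambda2_grid = lambda2_grid
        self.inner_folds = inner_folds
        self.seed = seed
        self.fit_intercept = fit_intercept
        self.standardize = standardize

    @classmethod
    def from_config(cls, config: ElasticNetConfig) -> "ElasticNetMap":
        return cls(
            lambda1_grid=config.lambda1_grid,
            lambda2_grid=config.lambda2_grid,
            inner_folds=config.inner_folds,
            seed=config.seed,
            fit_intercept=config.fit_intercept,
            standardize=config.standardize,
        )

    def _validate(self, X, Y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        y_1d = Y.ndim == 1
        if y_1d:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be row-aligned")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be finite")
        return X, Y, y_1d

    def fit(self, X, Y):
        X, Y, self._y_1d = self._validate(X, Y)
        grid1 = tuple(float(v) for v in self.lambda1_grid)
        grid2 = tuple(float(v) for v in self.lambda2_grid)
        if not grid1 or not grid2:
            raise ValueError("lambda grids must be non-empty")
        n = X.shape[0]

        if self.standardize:
            self._x_scale = X.std(axis=0)
            self._x_scale[self._x_scale == 0] = 1.0
        else:
            self._x_scale = np.ones(X.shape[1])
        Xs = X / self._x_scale

        pairs = [(l1, l2) for l1 in grid1 for l2 in grid2]
        if len(pairs) == 1:
            best = pairs[0]
            cv_per_output = np.full(Y.shape[1], np.nan)
            cv_table = {}
        else:
            folds = min(self.inner_folds, n)
            if folds < self.inner_folds:
                logger.warning(
                    "only %d samples: reducing inner folds from %d to %d",
                    n, self.inner_folds, folds,
                )
            kf = KFold(n_splits=folds, shuffle=True, random_state=self.seed)
            splits = list(kf.split(Xs))
            errors = {}
            per_output = {}
            for l1, l2 in pairs:
                sse = np.zeros(Y.shape[1])
                for tr, te in splits:
                    if len(tr) < 1:
                        continue
                    W, b = _solve(Xs[tr], Y[tr], l1, l2, self.fit_intercept)
                    resid = Y[te] - (Xs[te] @ W.T + b)
                    sse += np.sum(resid**2, axis=0)
                errors[(l1, l2)] = float(sse.sum())
                per_output[(l1, l2)] = sse / n
            # ties broken toward the larger total penalty
            best = min(pairs, key=lambda p: (errors[p], -(p[0] + p[1])))
            cv_per_output = per_output[best]
            cv_table = errors

        W, b = _solve(Xs, Y, best[0], best[1], self.fit_intercept)
        W = W / self._x_scale  # back to the original X scale
        self.weights_ = W
        self.offset_ = np.asarray(b).ravel()
        self.chosen_lambdas_ = (float(best[0]), float(best[1]))
        self.fit_diagnostics_ = {
            "inner_cv_mse_per_output": cv_per_output,
            "inner_cv_sse": cv_table,
        }
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        linmap = self.to_linear_map()
        out = predict_linear(linmap, X)
        return out[:, 0] if getattr(self, "_y_1d", False) else out

    def to_linear_map(self) -> LinearMap:
        if not hasattr(self, "weights_"):
            raise AttributeError("estimator is not fitted")
        return LinearMap(
            self.weights_, self.offset_, self.chosen_lambdas_, self.fit_diagnostics_
        )


def fit_elastic_net(
    X: np.ndarray, Y: np.ndarray, config: ElasticNetConfig | None = None
) -> LinearMap:
    """Functional wrapper around :class:`ElasticNetMap`."""
    config = config or ElasticNetConfig()
    est = ElasticNetMap.from_config(config)
    Y = np.asarray(Y, dtype=float)
    est.fit(X, Y if Y.ndim == 2 else Y[:, None])
    return est.to_linear_map()
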