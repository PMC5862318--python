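"""The base prediction algorithms behind a uniform fit/predict contract.

Five algorithms, each crossed with three variable sets (full indicators,
therapeutic groups, lasso-screened), give the default 15-learner library:

==============  =====================================================
tag             algorithm
==============  =====================================================
``nnet``        neural network, one hidden layer of two units
``lasso``       lasso regression, penalty by internal 10-fold CV
``ridge``       ridge regression, penalty by internal (LOO) CV
``tree``        regression tree with ANOVA (variance) splitting
``glm``         main-terms linear regression
==============  =====================================================

Learner ids are ``<tag>.<f|g|l>`` for the full / groups / lasso-screened
variable set.  Predictors are binary indicators and are deliberately not
standardized; the net standardizes the $-scale outcome internally for
optimizer stability and back-transforms its predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ALGORITHMS",
    "VARIABLE_SETS",
    "LearnerSpec",
    "FittedLearner",
    "MeanRegressor",
    "TwoUnitNeuralNet",
    "RidgeLOOCV",
    "AnovaRegressionTree",
    "make_estimator",
    "fit_learner",
    "predict_learner",
    "default_library",
]

ALGORITHMS = {
    "neural_net_2unit": "nnet",
    "lasso_cv": "lasso",
    "ridge_cv": "ridge",
    "regression_tree_anova": "tree",
    "linear_main_terms": "glm",
}

VARIABLE_SETS = {"full": "f", "groups": "g", "screened": "l"}


@dataclass(frozen=True)
class LearnerSpec:
    """One candidate learner: an algorithm applied to a variable set."""

    algorithm: str
    variable_set: str
    hyperparameters: tuple = ()  # optional (key, value) overrides

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.variable_set not in VARIABLE_SETS:
            raise ValueError(f"unknown variable set {self.variable_set!r}")

    @property
    def id(self) -> str:
        return f"{ALGORITHMS[self.algorithm]}.{VARIABLE_SETS[self.variable_set]}"


def default_library() -> list[LearnerSpec]:
    """All five algorithms crossed with all three variable sets (K = 15)."""
    return [
        LearnerSpec(alg, vs)
        for alg in ALGORITHMS
        for vs in VARIABLE_SETS
    ]


class MeanRegressor(BaseEstimator, RegressorMixin):
    """Degenerate fallback: predict the training mean everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        self.n_features_in_ = np.shape(X)[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return np.full(np.shape(X)[0], self.mean_)


class TwoUnitNeuralNet(BaseEstimator, RegressorMixin):
    """Single-hidden-layer (two unit) net with internal outcome scaling.

    Binary inputs are left as-is; the outcome is centered and scaled for
    L-BFGS stability and predictions are back-transformed to dollars.
    """

    def __init__(self, hidden_units: int = 2, max_iter: int = 100,
                 alpha: float = 1e-4, random_state: int | None = None):
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std())
        if self.y_scale_ == 0.0:
            self.net_ = None
            self.n_features_in_ = np.shape(X)[1]
            return self
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,),
            solver="lbfgs",
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(np.asarray(X, dtype=float), (y - self.y_mean_) / self.y_scale_)
        self.n_features_in_ = np.shape(X)[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        if self.net_ is None:
            return np.full(np.shape(X)[0], self.y_mean_)
        return self.y_mean_ + self.y_scale_ * self.net_.predict(np.asarray(X, dtype=float))


class RidgeLOOCV(BaseEstimator, RegressorMixin):
    """Ridge regression with the penalty chosen by leave-one-out CV.

    Solves min ||y - b0 - X beta||^2 + alpha ||beta||^2 over a log grid of
    penalties, scoring each by the exact closed-form leave-one-out error
    e_i = (y_i - yhat_i) / (1 - h_ii).  All penalties share one
    eigendecomposition of the (centered) Gram matrix, so the whole grid
    costs little more than a single fit.  The intercept is unpenalized.
    """

    def __init__(self, alphas: np.ndarray | None = None):
        self.alphas = alphas

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        alphas = self.alphas if self.alphas is not None else np.logspace(-2.0, 6.0, 17)
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean
        yc = y - y_mean
        G = Xc.T @ Xc
        lam, V = np.linalg.eigh(G)
        lam = np.maximum(lam, 0.0)
        B = Xc @ V
        B2 = B * B
        c = B.T @ yc
        best = (np.inf, None)
        for alpha in np.atleast_1d(alphas):
            d = 1.0 / (lam + alpha)
            yhat = B @ (d * c)
            # hat diagonal includes the intercept's 1/n leverage
            h = B2 @ d + 1.0 / len(y)
            resid = (yc - yhat) / np.clip(1.0 - h, 1e-12, None)
            loo = float(resid @ resid)
            if loo < best[0]:
                best = (loo, float(alpha))
        self.alpha_ = best[1]
        d = 1.0 / (lam + self.alpha_)
        self.coef_ = V @ (d * c)
        self.intercept_ = y_mean - float(x_mean @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


class AnovaRegressionTree(BaseEstimator, RegressorMixin):
    """Regression tree with variance-reduction (ANOVA) splitting.

    rpart-style controls: a split must reduce the total sum of squares by
    at least ``cp`` times the root sum of squares (the complexity
    parameter), with minimum node sizes matching common defaults.
    """

    def __init__(self, cp: float = 0.01, min_samples_split: int = 20,
                 min_samples_leaf: int = 7, max_depth: int = 30,
                 random_state: int | None = 0):
        self.cp = cp
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        # sklearn's weighted impurity-decrease threshold equals
        # cp * Var(y) when the decrease is measured per total sample
        self.tree_ = DecisionTreeRegressor(
            criterion="squared_error",
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            min_impurity_decrease=self.cp * float(np.var(y)),
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = np.shape(X)[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.tree_.predict(X)


def make_estimator(spec: LearnerSpec, seed: int | None = None) -> BaseEstimator:
    """Instantiate the sklearn estimator for a learner spec.

    ``seed`` controls only genuinely stochastic pieces (net weight
    initialization, internal CV fold shuffling); the linear learners and
    the tree are deterministic.
    """
    overrides = dict(spec.hyperparameters)
    if seed is None:
        seed = 0  # keep every learner deterministic by default
    if spec.algorithm == "linear_main_terms":
        est: BaseEstimator = LinearRegression()
    elif spec.algorithm == "lasso_cv":
        est = LassoCV(
            alphas=100,
            cv=KFold(n_splits=10, shuffle=True, random_state=seed),
            tol=1e-3,
            max_iter=2000,
        )
    elif spec.algorithm == "ridge_cv":
        est = RidgeLOOCV()
    elif spec.algorithm == "regression_tree_anova":
        est = AnovaRegressionTree(random_state=seed)
    elif spec.algorithm == "neural_net_2unit":
        est = TwoUnitNeuralNet(random_state=seed)
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(spec.algorithm)
    if overrides:
        est.set_params(**overrides)
    return est


@dataclass
class FittedLearner:
    """A fitted candidate: the estimator, its spec, its training columns."""

    estimator: BaseEstimator
    spec: LearnerSpec
    columns: tuple[str, ...]
    fallback: bool = False  # True when the mean-predicting fallback was used


def fit_learner(
    spec: LearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int | None = None,
) -> FittedLearner:
    """Fit one learner; degrade gracefully to a mean fit on failure.

    A constant outcome (or any estimator error) yields a mean-predicting
    degenerate fit with a logged warning rather than a crash, so a single
    pathological fold cannot abort an ensemble run.
    """
    y = np.asarray(y, dtype=float)
    columns = tuple(X.columns)
    values = X.to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn(f"constant outcome for learner {spec.id}; using mean fit")
        return FittedLearner(MeanRegressor().fit(values, y), spec, columns, fallback=True)
    est = make_estimator(spec, seed=seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(values, y)
    except Exception as exc:  # noqa: BLE001 - fallback is the contract
        warnings.warn(f"learner {spec.id} failed ({exc!r}); using mean fit")
        return FittedLearner(MeanRegressor().fit(values, y), spec, columns, fallback=True)
    return FittedLearner(est, spec, columns)


def predict_learner(fit: FittedLearner, X: pd.DataFrame) -> np.ndarray:
    """Predict with a fitted learner; columns may arrive in any order."""
    missing = [c for c in fit.columns if c not in X.columns]
    extra = [c for c in X.columns if c not in fit.columns]
    if missing or extra:
        raise ValueError(
            f"column mismatch for learner {fit.spec.id}: missing={missing[:5]} extra={extra[:5]}"
        )
    values = X[list(fit.columns)].to_numpy(dtype=float)
    pred = np.asarray(fit.estimator.predict(values), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError(f"non-finite predictions from learner {fit.spec.id}")
    return pred
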