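"""Super learner: out-of-fold stacking with convex ensemble weights.

The three-step construction:

1. Assign enrollees to V folds; fit every candidate learner on each
   fold's training portion and predict its validation portion, giving an
   n x K matrix Z of out-of-fold predictions.
2. Estimate the ensemble weights alpha by regressing the outcome U on Z
   under a convexity constraint (alpha >= 0, sum alpha = 1), i.e. the
   simplex-constrained least-squares problem
   min_alpha ||U - Z alpha||^2.
3. Refit all K learners on the full data and combine them with alpha.

Learners using the screened variable set share one screened set per fold,
computed from that fold's training rows only (the screener defines a
variable set, not a learner step); the full-data refit re-screens on all
rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._rng import child_seed, substream
from .learners import (
    FittedLearner,
    LearnerSpec,
    default_library,
    fit_learner,
    predict_learner,
)
from .screening import VariableSet, screen_within_fold

__all__ = [
    "FoldAssignment",
    "CVPredictionMatrix",
    "EnsembleWeights",
    "assign_folds",
    "cv_predictions",
    "estimate_weights",
    "SuperLearnerRegressor",
    "fit_super_learner",
]

DEFAULT_FORCED = ("tc_hiv_antivirals", "tc_ms_biologics")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """A balanced random partition of rows into V folds (labels 0..V-1)."""

    labels: np.ndarray
    V: int
    seed: int | None = None

    def train_rows(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.labels != v)

    def validation_rows(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.labels == v)


@dataclass
class CVPredictionMatrix:
    """Out-of-fold predictions: Z[i, k] never saw row i's outcome."""

    Z: np.ndarray  # n x K
    learner_ids: tuple[str, ...]
    fold_screened: dict[int, VariableSet] = field(default_factory=dict)


@dataclass(frozen=True)
class EnsembleWeights:
    """Convex coefficients over the K learners and the achieved objective."""

    alpha: np.ndarray
    objective: float  # mean squared error of the stacked CV predictions


def assign_folds(n: int, V: int, seed: int | None = None) -> FoldAssignment:
    """Uniformly random balanced fold assignment (sizes differ by <= 1)."""
    if not 2 <= V <= n:
        raise ValueError(f"need 2 <= V <= n, got V={V}, n={n}")
    rng = substream(seed if seed is not None else 0, "folds")
    labels = np.repeat(np.arange(V), np.diff(np.linspace(0, n, V + 1).astype(int)))
    rng.shuffle(labels)
    return FoldAssignment(labels=labels, V=V, seed=seed)


def _variable_columns(
    spec: LearnerSpec,
    variable_sets: dict[str, tuple[str, ...]],
    screened: VariableSet | None,
) -> list[str]:
    if spec.variable_set == "screened":
        if screened is None:
            raise ValueError("screened variable set requested but no screener result")
        return list(screened.columns)
    return list(variable_sets[spec.variable_set])


def cv_predictions(
    specs: list[LearnerSpec],
    X: pd.DataFrame,
    y: np.ndarray,
    folds: FoldAssignment,
    variable_sets: dict[str, tuple[str, ...]],
    screen_cap: int = 10,
    forced: tuple[str, ...] = (),
    seed: int | None = None,
) -> CVPredictionMatrix:
    """Fill the n x K out-of-fold prediction matrix.

    A learner that fails inside a fold contributes that fold's training
    mean for its validation rows (with a warning) instead of aborting.
    """
    if not specs:
        raise ValueError("no learner specs given")
    y = np.asarray(y, dtype=float)
    n = len(X)
    Z = np.empty((n, len(specs)))
    needs_screen = any(s.variable_set == "screened" for s in specs)
    fold_screened: dict[int, VariableSet] = {}

    for v in range(folds.V):
        train = folds.train_rows(v)
        val = folds.validation_rows(v)
        screened = None
        if needs_screen:
            screened = screen_within_fold(X, y, train, cap=screen_cap, forced=forced)
            fold_screened[v] = screened
        X_train, X_val = X.iloc[train], X.iloc[val]
        y_train = y[train]
        for k, spec in enumerate(specs):
            cols = _variable_columns(spec, variable_sets, screened)
            fit_seed = None if seed is None else child_seed(seed, "fit", spec.id, str(v))
            logger.info("fold %d: fitting learner %s on %d columns", v, spec.id, len(cols))
            fit = fit_learner(spec, X_train[cols], y_train, seed=fit_seed)
            try:
                Z[val, k] = predict_learner(fit, X_val[cols])
            except ValueError as exc:
                warnings.warn(f"learner {spec.id} failed in fold {v} ({exc}); mean fallback")
                Z[val, k] = y_train.mean()
    return CVPredictionMatrix(
        Z=Z, learner_ids=tuple(s.id for s in specs), fold_screened=fold_screened
    )


def _simplex_objective(alpha: np.ndarray, A: np.ndarray, b: np.ndarray, c: float) -> float:
    return float(alpha @ A @ alpha - 2.0 * b @ alpha + c)


def estimate_weights(U: np.ndarray, Z: np.ndarray | CVPredictionMatrix) -> EnsembleWeights:
    """Convex stacking weights: argmin ||U - Z alpha||^2 on the simplex.

    Solved as a quadratic program (SLSQP with analytic gradient from the
    precomputed Gram).  A degenerate matrix whose columns are all
    identical yields uniform weights with a warning.  The returned weights
    are guaranteed no worse (in CV squared error) than any single learner.
    """
    if isinstance(Z, CVPredictionMatrix):
        Z = Z.Z
    U = np.asarray(U, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != U.shape[0]:
        raise ValueError("Z must be n x K with n matching U")
    if not np.all(np.isfinite(Z)) or not np.all(np.isfinite(U)):
        raise ValueError("non-finite values in weight estimation")
    n, K = Z.shape
    if K == 1:
        resid = U - Z[:, 0]
        return EnsembleWeights(alpha=np.array([1.0]), objective=float(resid @ resid / n))

    A = Z.T @ Z / n
    b = Z.T @ U / n
    c = float(U @ U / n)

    if np.ptp(Z, axis=1).max() == 0.0:
        warnings.warn("all learner prediction columns identical; uniform weights")
        alpha = np.full(K, 1.0 / K)
        return EnsembleWeights(alpha=alpha, objective=_simplex_objective(alpha, A, b, c))

    x0 = np.full(K, 1.0 / K)
    res = minimize(
        lambda a: _simplex_objective(a, A, b, c),
        x0,
        jac=lambda a: 2.0 * (A @ a - b),
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones_like(a)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    alpha = np.clip(res.x, 0.0, None)
    alpha /= alpha.sum()

    # exact safeguard: never worse than any canonical vertex or uniform
    candidates = [alpha, x0] + [np.eye(K)[k] for k in range(K)]
    objectives = [_simplex_objective(a, A, b, c) for a in candidates]
    best = int(np.argmin(objectives))
    return EnsembleWeights(alpha=candidates[best], objective=objectives[best])


class SuperLearnerRegressor(BaseEstimator, RegressorMixin):
    """Convex-stacked ensemble of the candidate learner library.

    Parameters
    ----------
    library : list of LearnerSpec or None
        Candidate learners; ``None`` uses the default 15-learner library
        (five algorithms x three variable sets).
    variable_sets : dict name -> columns, or None
        Columns of the ``full`` and ``groups`` sets.  ``None`` treats all
        predictor columns as the ``full`` set (and forbids ``groups``
        learners).
    V : int
        Number of stacking cross-validation folds.
    screen_cap, forced : screener configuration for ``screened`` learners.
    random_state : int or None
        Seed for fold assignment and stochastic learners.

    Attributes
    ----------
    learners_ : list of FittedLearner (full-data refits)
    weights_ : EnsembleWeights
    cv_matrix_ : CVPredictionMatrix (the stacking Z)
    folds_ : FoldAssignment
    screened_full_ : VariableSet or None (full-data re-screen)
    """

    def __init__(
        self,
        library: list[LearnerSpec] | None = None,
        variable_sets: dict[str, tuple[str, ...]] | None = None,
        V: int = 10,
        screen_cap: int = 10,
        forced: tuple[str, ...] = DEFAULT_FORCED,
        random_state: int | None = None,
    ):
        self.library = library
        self.variable_sets = variable_sets
        self.V = V
        self.screen_cap = screen_cap
        self.forced = forced
        self.random_state = random_state

    def _resolved_library(self) -> list[LearnerSpec]:
        return list(self.library) if self.library is not None else default_library()

    def _resolved_sets(self, X: pd.DataFrame) -> dict[str, tuple[str, ...]]:
        if self.variable_sets is not None:
            return dict(self.variable_sets)
        return {"full": tuple(X.columns)}

    def fit(self, X: pd.DataFrame, y) -> "SuperLearnerRegressor":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        specs = self._resolved_library()
        vsets = self._resolved_sets(X)
        seed = self.random_state if self.random_state is not None else 0
        forced = tuple(f for f in self.forced if f in X.columns)

        self.folds_ = assign_folds(len(X), self.V, seed=child_seed(seed, "inner_folds"))
        self.cv_matrix_ = cv_predictions(
            specs, X, y, self.folds_, vsets,
            screen_cap=self.screen_cap, forced=forced, seed=seed,
        )
        self.weights_ = estimate_weights(y, self.cv_matrix_)

        # step 3: full-data refits (screened learners re-screen on all rows)
        screened_full = None
        if any(s.variable_set == "screened" for s in specs):
            screened_full = screen_within_fold(
                X, y, np.arange(len(X)), cap=self.screen_cap, forced=forced
            )
        self.screened_full_ = screened_full

        learners: list[FittedLearner] = []
        kept = np.ones(len(specs), dtype=bool)
        for k, spec in enumerate(specs):
            cols = _variable_columns(spec, vsets, screened_full)
            fit_seed = child_seed(seed, "fit", spec.id, "full")
            logger.info("full data: fitting learner %s on %d columns", spec.id, len(cols))
            try:
                learners.append(fit_learner(spec, X[cols], y, seed=fit_seed))
            except Exception as exc:  # noqa: BLE001
                warnings.warn(
                    f"learner {spec.id} failed on the full data ({exc!r}); "
                    "dropped with weight renormalization"
                )
                kept[k] = False
        alpha = self.weights_.alpha[kept]
        if alpha.sum() == 0:
            alpha = np.full(kept.sum(), 1.0 / kept.sum())
        else:
            alpha = alpha / alpha.sum()
        self.learners_ = learners
        self.alpha_ = alpha
        self.learner_ids_ = tuple(s.id for k, s in enumerate(specs) if kept[k])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict_candidates(self, X: pd.DataFrame) -> np.ndarray:
        """n x K matrix of every refit learner's predictions."""
        check_is_fitted(self, "learners_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=list(self.feature_names_in_))
        preds = [predict_learner(f, X[list(f.columns)]) for f in self.learners_]
        return np.column_stack(preds)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """The convex combination sum_k alpha_k * learner_k(x)."""
        return self.predict_candidates(X) @ self.alpha_

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "learners_")
        return {
            "learner_ids": list(self.learner_ids_),
            "weights": [float(a) for a in self.alpha_],
            "cv_objective": float(self.weights_.objective),
            "V": self.V,
            "screen_cap": self.screen_cap,
            "forced": list(self.forced),
            "screened_full": (
                self.screened_full_.provenance | {"columns": list(self.screened_full_.columns)}
                if self.screened_full_ is not None
                else None
            ),
            "fold_screened": {
                str(v): list(vs.columns) for v, vs in self.cv_matrix_.fold_screened.items()
            },
        }


def fit_super_learner(
    X: pd.DataFrame,
    y: np.ndarray,
    library: list[LearnerSpec] | None = None,
    variable_sets: dict[str, tuple[str, ...]] | None = None,
    V: int = 10,
    screen_cap: int = 10,
    forced: tuple[str, ...] = DEFAULT_FORCED,
    seed: int | None = None,
) -> SuperLearnerRegressor:
    """Functional wrapper over :class:`SuperLearnerRegressor`."""
    return SuperLearnerRegressor(
        library=library,
        variable_sets=variable_sets,
        V=V,
        screen_cap=screen_cap,
        forced=forced,
        random_state=seed,
    ).fit(X, y)
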