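"""Capped lasso variable screener with forced inclusions.

The screened variable set is chosen by walking the lasso regularization
path from the largest penalty downward and keeping the largest active set
whose size does not exceed the cap (ten by default).  When several
variables enter simultaneously and push the active set past the cap, the
screener backs off to the larger-penalty knot, excluding the tied
entrants.  The data-driven selection is then augmented with forced
indicators — HIV antivirals and multiple-sclerosis biologicals, whose
therapies are costly enough to warrant inclusion regardless of what the
data select.

The screener is a deterministic function of (X, y, cap, forced): no
randomness is involved, the intercept is always unpenalized and never
counts against the cap, and binary predictors are not standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path

__all__ = ["VariableSet", "CapLassoScreener", "screen_variables", "screen_within_fold"]


@dataclass(frozen=True)
class VariableSet:
    """A named predictor set with provenance for screened selections."""

    name: str
    columns: tuple[str, ...]
    provenance: dict = field(default_factory=dict)


class CapLassoScreener(BaseEstimator):
    """Select at most ``cap`` variables on the lasso path, plus forced ids.

    Parameters
    ----------
    cap : int
        Maximum number of data-selected variables (pre-augmentation).
    forced : sequence of str
        Column names always unioned into the selection.
    n_alphas, eps : path resolution
        Logarithmic grid of ``n_alphas`` knots from the smallest penalty
        with an empty active set down to ``eps`` times that penalty.

    Attributes (after fit)
    ----------------------
    selected_ : tuple of str — final columns (data-selected + forced).
    data_selected_ : tuple of str — the pre-augmentation selection.
    forced_added_ : tuple of str — forced ids not already selected.
    alpha_ : float or None — the penalty whose active set was returned.
    """

    def __init__(self, cap: int = 10, forced: tuple[str, ...] = (),
                 n_alphas: int = 100, eps: float = 1e-3):
        self.cap = cap
        self.forced = forced
        self.n_alphas = n_alphas
        self.eps = eps

    def fit(self, X: pd.DataFrame, y):
        if self.cap < 0:
            raise ValueError("cap must be >= 0")
        columns = list(X.columns)
        missing = [f for f in self.forced if f not in columns]
        if missing:
            raise ValueError(f"forced ids not among predictors: {missing}")
        y = np.asarray(y, dtype=float)
        values = X.to_numpy(dtype=float)

        selected: list[str] = []
        alpha_used: float | None = None
        if self.cap > 0 and np.ptp(y) > 0 and values.size and np.any(values != values[0]):
            # centered path = unpenalized intercept; no standardization
            Xc = values - values.mean(axis=0)
            yc = y - y.mean()
            alphas, coefs, _ = lasso_path(Xc, yc, alphas=self.n_alphas, eps=self.eps)
            active = coefs != 0.0  # p x n_alphas, alphas descending
            sizes = active.sum(axis=0)
            eligible = np.flatnonzero((sizes >= 1) & (sizes <= self.cap))
            if eligible.size:
                best = eligible[np.argmax(sizes[eligible])]
                # ties in size resolve to the smallest penalty (most fitted)
                ties = eligible[sizes[eligible] == sizes[best]]
                best = int(ties.max())
                alpha_used = float(alphas[best])
                selected = [columns[j] for j in np.flatnonzero(active[:, best])]
            # else: entrants jumped straight past the cap; back off to the
            # larger-penalty side, i.e. the empty set, excluding the ties
        if self.cap == 0 and not self.forced:
            warnings.warn("cap=0 with no forced ids: empty variable set")

        forced_added = tuple(f for f in self.forced if f not in selected)
        self.data_selected_ = tuple(selected)
        self.forced_added_ = forced_added
        self.alpha_ = alpha_used
        self.selected_ = tuple(selected) + forced_added
        self.n_features_in_ = values.shape[1]
        self.feature_names_in_ = np.asarray(columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[list(self.selected_)]

    def variable_set(self) -> VariableSet:
        return VariableSet(
            name="screened",
            columns=self.selected_,
            provenance={
                "lambda": self.alpha_,
                "data_selected": list(self.data_selected_),
                "forced_added": list(self.forced_added_),
                "cap": self.cap,
            },
        )


def screen_variables(
    X: pd.DataFrame,
    y,
    cap: int = 10,
    forced: tuple[str, ...] = (),
    n_alphas: int = 100,
    eps: float = 1e-3,
) -> VariableSet:
    """Screen on the full data; see :class:`CapLassoScreener`."""
    return CapLassoScreener(cap=cap, forced=tuple(forced), n_alphas=n_alphas, eps=eps).fit(
        X, y
    ).variable_set()


def screen_within_fold(
    X: pd.DataFrame,
    y,
    train_rows: np.ndarray,
    cap: int = 10,
    forced: tuple[str, ...] = (),
    n_alphas: int = 100,
    eps: float = 1e-3,
) -> VariableSet:
    """Screen using only a fold's training rows; validation rows never leak."""
    y = np.asarray(y, dtype=float)
    return screen_variables(
        X.iloc[train_rows], y[train_rows], cap=cap, forced=forced, n_alphas=n_alphas, eps=eps
    )
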