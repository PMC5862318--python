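"""Cross-validated performance metrics and the nested-CV harness.

The whole super learner (inner folds, per-fold screening, weight
estimation, refit) is itself evaluated with an outer layer of V-fold
cross-validation; pooled out-of-fold predictions give CV MSE and CV R^2
for the ensemble and every candidate learner, plus relative efficiencies
(learner R^2 over ensemble R^2).  A falsification harness reruns the full
pipeline on an outcome drawn independently of every predictor: any
material R^2 there indicates leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed, substream
from .ensemble import (
    DEFAULT_FORCED,
    SuperLearnerRegressor,
    assign_folds,
)
from .learners import LearnerSpec, default_library

__all__ = [
    "MetricsReport",
    "cv_mse",
    "cv_r2",
    "relative_efficiency",
    "nested_cv_evaluate",
    "falsification_test",
    "residual_report",
]


def cv_mse(U: np.ndarray, z: np.ndarray) -> float:
    """Mean squared error (1/n) sum (U_i - z_i)^2, in $^2."""
    U = np.asarray(U, dtype=float)
    z = np.asarray(z, dtype=float)
    if U.shape != z.shape:
        raise ValueError("outcome and prediction vectors must have equal length")
    if U.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((U - z) ** 2))


def cv_r2(U: np.ndarray, z: np.ndarray) -> float:
    """1 - sum (U_i - z_i)^2 / sum (U_i - U-bar)^2; negative when worse than the mean."""
    U = np.asarray(U, dtype=float)
    z = np.asarray(z, dtype=float)
    if U.shape != z.shape:
        raise ValueError("outcome and prediction vectors must have equal length")
    denom = float(np.sum((U - U.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("constant outcome: R^2 undefined")
    return 1.0 - float(np.sum((U - z) ** 2)) / denom


def relative_efficiency(r2_k: float, r2_sl: float) -> float:
    """A learner's CV R^2 relative to the ensemble's; NaN when undefined."""
    if r2_sl == 0.0:
        warnings.warn("ensemble CV R^2 is zero; relative efficiency undefined")
        return float("nan")
    return r2_k / r2_sl


@dataclass
class MetricsReport:
    """Per-learner and ensemble CV metrics plus diagnostics.

    ``table`` rows are learner ids plus ``"SL"``; columns ``cv_mse``
    ($^2), ``cv_r2`` (fraction) and ``relative_efficiency`` (fraction,
    learner over ensemble).
    """

    table: pd.DataFrame
    outer_predictions: pd.DataFrame  # id, fold, per-learner and SL columns
    residuals: dict
    outer_weights: list[list[float]]
    notes: dict = field(default_factory=dict)

    @property
    def sl_r2(self) -> float:
        return float(self.table.loc["SL", "cv_r2"])

    def to_json_dict(self) -> dict:
        return {
            "metrics": {
                idx: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for idx, row in self.table.iterrows()
            },
            "residual_summary": self.residuals,
            "outer_weights": self.outer_weights,
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    def to_text(self) -> str:
        """Three-panel text table: CV R^2, CV MSE, relative efficiency."""
        lines = [f"{'learner':<10}{'CV R^2':>10}{'CV MSE':>16}{'rel. eff.':>11}"]
        for idx, row in self.table.iterrows():
            re_s = "-" if pd.isna(row["relative_efficiency"]) else f"{row['relative_efficiency']:.3f}"
            lines.append(
                f"{idx:<10}{row['cv_r2']:>10.4f}{row['cv_mse']:>16.1f}{re_s:>11}"
            )
        return "\n".join(lines)


def residual_report(U: np.ndarray, predictions: np.ndarray, mad_threshold: float = 6.0) -> dict:
    """Residuals U - prediction with robust extreme-outlier flagging.

    An observation is flagged when its residual sits more than
    ``mad_threshold`` scaled MADs (1.4826 x median absolute deviation)
    from the median residual.
    """
    U = np.asarray(U, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if U.shape != predictions.shape:
        raise ValueError("outcome and prediction vectors must have equal length")
    resid = U - predictions
    med = float(np.median(resid))
    mad = float(np.median(np.abs(resid - med))) * 1.4826
    if mad == 0.0:
        flags = np.zeros(resid.size, dtype=bool)
    else:
        flags = np.abs(resid - med) > mad_threshold * mad
    return {
        "mean": float(resid.mean()),
        "median": med,
        "scaled_mad": mad,
        "n_flagged": int(flags.sum()),
        "flagged_rows": np.flatnonzero(flags).tolist()[:50],
        "max_abs_residual": float(np.abs(resid).max()) if resid.size else 0.0,
    }


def nested_cv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    library: list[LearnerSpec] | None = None,
    variable_sets: dict[str, tuple[str, ...]] | None = None,
    V_outer: int = 10,
    V_inner: int = 10,
    screen_cap: int = 10,
    forced: tuple[str, ...] = DEFAULT_FORCED,
    seed: int = 0,
) -> MetricsReport:
    """Outer V-fold CV of the complete super learner.

    Each outer training set runs the whole pipeline — inner fold
    assignment, per-fold screening, weight estimation, full refit — and
    predicts its outer validation fold with the ensemble and with every
    refit candidate.  Metrics pool all outer-fold predictions.
    """
    y = np.asarray(y, dtype=float)
    specs = list(library) if library is not None else default_library()
    ids = [s.id for s in specs]
    n = len(X)
    outer = assign_folds(n, V_outer, seed=child_seed(seed, "outer_folds"))

    Z_outer = np.empty((n, len(specs)))
    sl_pred = np.empty(n)
    outer_weights: list[list[float]] = []
    failures: dict[str, list[int]] = {}

    for v in range(outer.V):
        train = outer.train_rows(v)
        val = outer.validation_rows(v)
        sl = SuperLearnerRegressor(
            library=specs,
            variable_sets=variable_sets,
            V=V_inner,
            screen_cap=screen_cap,
            forced=forced,
            random_state=child_seed(seed, "outer_fit", str(v)),
        ).fit(X.iloc[train], y[train])
        cand = sl.predict_candidates(X.iloc[val])
        sl_pred[val] = cand @ sl.alpha_
        if len(sl.learner_ids_) != len(specs):  # a learner was dropped
            kept = {lid: j for j, lid in enumerate(sl.learner_ids_)}
            padded = np.tile(y[train].mean(), (len(val), len(specs)))
            for k, lid in enumerate(ids):
                if lid in kept:
                    padded[:, k] = cand[:, kept[lid]]
                else:
                    failures.setdefault(lid, []).append(v)
            cand = padded
        Z_outer[val] = cand
        outer_weights.append([float(a) for a in sl.alpha_])

    rows = {}
    sl_r2 = cv_r2(y, sl_pred)
    for k, lid in enumerate(ids):
        r2_k = cv_r2(y, Z_outer[:, k])
        rows[lid] = {
            "cv_mse": cv_mse(y, Z_outer[:, k]),
            "cv_r2": r2_k,
            "relative_efficiency": (r2_k / sl_r2) if sl_r2 != 0.0 else float("nan"),
        }
    rows["SL"] = {
        "cv_mse": cv_mse(y, sl_pred),
        "cv_r2": sl_r2,
        "relative_efficiency": 1.0 if sl_r2 != 0.0 else float("nan"),
    }
    table = pd.DataFrame(rows).T

    outer_predictions = pd.DataFrame(Z_outer, columns=ids)
    outer_predictions.insert(0, "fold", outer.labels)
    outer_predictions["SL"] = sl_pred

    return MetricsReport(
        table=table,
        outer_predictions=outer_predictions,
        residuals=residual_report(y, sl_pred),
        outer_weights=outer_weights,
        notes={"V_outer": V_outer, "V_inner": V_inner, "n": n,
               "failures": {k: v for k, v in failures.items()}},
    )


def falsification_test(
    X: pd.DataFrame,
    y: np.ndarray,
    library: list[LearnerSpec] | None = None,
    variable_sets: dict[str, tuple[str, ...]] | None = None,
    V_outer: int = 10,
    V_inner: int = 10,
    screen_cap: int = 10,
    forced: tuple[str, ...] = DEFAULT_FORCED,
    seed: int = 0,
) -> tuple[float, MetricsReport]:
    """Rerun the nested evaluation on an outcome independent of X.

    The simulated outcome is Gaussian with the empirical mean and SD of
    the real outcome (same marginal scale, no relationship to any
    predictor).  Returns the ensemble's outer CV R^2, which should be
    indistinguishable from zero; anything else flags leakage.
    """
    y = np.asarray(y, dtype=float)
    sd = float(y.std())
    if sd == 0.0:
        raise ValueError("outcome has zero variance; falsification undefined")
    rng = substream(seed, "falsification")
    y_sim = rng.normal(float(y.mean()), sd, size=len(y))
    report = nested_cv_evaluate(
        X, y_sim,
        library=library, variable_sets=variable_sets,
        V_outer=V_outer, V_inner=V_inner,
        screen_cap=screen_cap, forced=forced, seed=seed,
    )
    report.notes["falsification"] = True
    return report.sl_r2, report
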