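"""End-to-end pipeline: generate -> derive -> ensemble -> evaluate.

`RunConfig` is a fully serializable snapshot; a run is bit-reproducible
from it (all randomness flows from the single ``seed`` through named
substreams: cohort, inner folds, outer folds, net initialization,
falsification outcome).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    DrugVocabulary,
    EnrolleeTable,
    cohort_summary,
    drop_empty_variables,
    generate_cohort,
    generate_vocabulary,
    load_cohort,
    save_cohort,
)
from .ensemble import DEFAULT_FORCED, SuperLearnerRegressor
from .evaluate import MetricsReport, falsification_test, nested_cv_evaluate
from .learners import ALGORITHMS, VARIABLE_SETS, LearnerSpec, default_library
from .payment import compute_unprofitability

__all__ = ["RunConfig", "run_pipeline", "derive_payments", "build_library"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    out: str = "run"
    n: int = 10_000
    V_inner: int = 10
    V_outer: int = 10
    screen_cap: int = 10
    forced: tuple[str, ...] = DEFAULT_FORCED
    algorithms: tuple[str, ...] = tuple(ALGORITHMS)
    variable_sets: tuple[str, ...] = tuple(VARIABLE_SETS)
    falsify: bool = False
    drop_empty: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("forced", "algorithms", "variable_sets"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        for key in ("forced", "algorithms", "variable_sets"):
            doc[key] = list(doc[key])
        return doc

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n=self.n, seed=self.seed, **self.cohort)


def build_library(config: RunConfig) -> list[LearnerSpec]:
    return [
        LearnerSpec(alg, vs)
        for alg in config.algorithms
        for vs in config.variable_sets
    ]


def derive_payments(table: EnrolleeTable) -> pd.DataFrame:
    """Cohort frame with appended premium/transfer/revenue/profit/unprofit columns."""
    comp = compute_unprofitability(table.costs, table.risk_scores)
    frame = table.frame.copy()
    frame["premium"] = comp.premium
    frame["transfer"] = comp.transfer
    frame["revenue"] = comp.revenue
    frame["profit"] = comp.profit
    frame["unprofit"] = comp.unprofitability
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out``.

    Artifacts: vocabulary.json, cohort.csv, cohort_payments.csv,
    superlearner.json, predictions.csv, metrics.json,
    screened_variables.json, run_log.txt.  Returns a summary dict.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("unprofit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    try:
        logger.info("run config hash %s", config.config_hash())
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

        t0 = time.time()
        cohort_cfg = config.cohort_config()
        vocab = generate_vocabulary(cohort_cfg)
        table = generate_cohort(vocab, cohort_cfg)
        if config.drop_empty:
            table = drop_empty_variables(table)
            vocab = table.vocab
        vocab.to_json(out / "vocabulary.json")
        save_cohort(table, out / "cohort.csv")
        timings["generate"] = time.time() - t0
        logger.info("generated cohort n=%d, %d indicators", table.n, len(table.indicator_columns))

        t0 = time.time()
        payments = derive_payments(table)
        payments.to_csv(out / "cohort_payments.csv", index=False)
        U = payments["unprofit"].to_numpy()
        timings["derive"] = time.time() - t0

        t0 = time.time()
        library = build_library(config)
        X = table.X[list(vocab.variable_sets()["full"])]
        sl = SuperLearnerRegressor(
            library=library,
            variable_sets=vocab.variable_sets(),
            V=config.V_inner,
            screen_cap=config.screen_cap,
            forced=tuple(f for f in config.forced if f in X.columns),
            random_state=config.seed,
        ).fit(X, U)
        (out / "superlearner.json").write_text(json.dumps(sl.to_json_dict(), indent=1))
        pd.DataFrame({"id": table.frame["id"], "prediction": sl.predict(X)}).to_csv(
            out / "predictions.csv", index=False
        )
        screened_doc = sl.to_json_dict()
        (out / "screened_variables.json").write_text(
            json.dumps(
                {"full_data": screened_doc["screened_full"],
                 "per_fold": screened_doc["fold_screened"]},
                indent=1,
            )
        )
        timings["fit"] = time.time() - t0

        t0 = time.time()
        report = nested_cv_evaluate(
            X, U,
            library=library,
            variable_sets=vocab.variable_sets(),
            V_outer=config.V_outer,
            V_inner=config.V_inner,
            screen_cap=config.screen_cap,
            forced=tuple(f for f in config.forced if f in X.columns),
            seed=config.seed,
        )
        result = {
            "config_hash": config.config_hash(),
            "summary": cohort_summary(table),
            "weights": dict(zip(sl.learner_ids_, map(float, sl.alpha_))),
            "sl_cv_r2": report.sl_r2,
        }
        if config.falsify:
            fals_r2, _ = falsification_test(
                X, U,
                library=library,
                variable_sets=vocab.variable_sets(),
                V_outer=config.V_outer,
                V_inner=config.V_inner,
                screen_cap=config.screen_cap,
                forced=tuple(f for f in config.forced if f in X.columns),
                seed=config.seed,
            )
            report.notes["falsification_cv_r2"] = fals_r2
            result["falsification_cv_r2"] = fals_r2
        report.to_json(out / "metrics.json")
        (out / "metrics.txt").write_text(report.to_text() + "\n")
        timings["evaluate"] = time.time() - t0

        for stage, secs in timings.items():
            logger.info("stage %-9s %.2fs", stage, secs)
        result["timings"] = timings
        (out / "result.json").write_text(json.dumps(result, indent=1))
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
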