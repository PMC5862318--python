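"""Synthetic claims-cohort generator.

The real analysis runs on proprietary commercial claims: per enrollee, one
annual total cost, one diagnosis-based risk score, and a few hundred binary
drug-utilization indicators (therapeutic classes nested in therapeutic
groups, plus generic-status and maintenance-category flags).  This module
generates cohorts with that structure so every downstream stage — payment
formulas, screening, the super learner, nested cross-validation — is
testable end to end without any restricted data.

The generator's key design point is the *risk-capture* mechanism: each
therapeutic class carries an additive expected-cost effect, and a per-class
fraction of that effect is reflected in the enrollee's risk score.  Classes
with capture below one leave residual signal in unprofitability (cost minus
risk-adjusted revenue), which is exactly the phenomenon the prediction
pipeline is built to detect.  With full capture and no noise, risk
adjustment neutralizes class membership in expectation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "DrugVocabulary",
    "CohortConfig",
    "EnrolleeTable",
    "generate_vocabulary",
    "generate_cohort",
    "drop_empty_variables",
    "save_cohort",
    "load_cohort",
    "cohort_summary",
]

GENERIC_FLAG_IDS = (
    "gx_single_source_brand",
    "gx_multi_source_brand",
    "gx_branded_generic",
    "gx_single_source_generic",
    "gx_multi_source_generic",
    "gx_otc",
    "gx_combination_product",
    "gx_repackaged",
)

MAINTENANCE_FLAG_IDS = (
    "mx_chronic",
    "mx_acute",
    "mx_both",
    "mx_intermittent",
    "mx_unclassified",
)

HIV_CLASS_ID = "tc_hiv_antivirals"
MS_CLASS_ID = "tc_ms_biologics"

# default residual-signal classes: moderately prevalent therapies whose cost
# effect the risk score only partly captures (the analysis's target signal)
RESIDUAL_CLASS_INDICES = (5, 10, 15, 20, 25, 30, 35, 45, 50, 55, 60, 65)


# --------------------------------------------------------------------------
# vocabulary
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugVocabulary:
    """The hierarchy of drug-indicator variables.

    Therapeutic classes are the atomic indicators; each class belongs to
    exactly one therapeutic group, one generic-status category and one
    maintenance category.  Group / generic / maintenance indicators for an
    enrollee are the OR of the class indicators mapped to them.

    Attributes
    ----------
    class_ids : tuple of str
        Therapeutic-class identifiers (the atomic binary variables).
    group_of : mapping class id -> group id.
    generic_flags, maintenance_flags : tuple of str
        Identifiers of the generic-status and maintenance-category
        indicators.
    forced_ids : tuple of str
        Class ids always added to the screened variable set (HIV
        antivirals and multiple-sclerosis biologicals by default).
    generic_of, maintenance_of : mapping class id -> flag id.
    """

    class_ids: tuple[str, ...]
    group_of: Mapping[str, str]
    generic_flags: tuple[str, ...]
    maintenance_flags: tuple[str, ...]
    forced_ids: tuple[str, ...]
    generic_of: Mapping[str, str]
    maintenance_of: Mapping[str, str]
    # groups whose indicator column was removed (e.g. singleton groups that
    # duplicate their only class); classes still map to them in group_of
    excluded_group_indicators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in self.class_ids if c not in self.group_of]
        if missing:
            raise ValueError(f"classes without a group: {missing[:5]}")
        if not set(self.forced_ids) <= set(self.class_ids):
            raise ValueError("forced_ids must be a subset of class_ids")
        everything = (
            list(self.class_ids)
            + list(self.group_ids)
            + list(self.generic_flags)
            + list(self.maintenance_flags)
        )
        if len(set(everything)) != len(everything):
            raise ValueError("identifiers must be unique across categories")

    @property
    def group_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.class_ids:
            g = self.group_of[c]
            if g not in self.excluded_group_indicators:
                seen.setdefault(g, None)
        return tuple(seen)

    def classes_in_group(self, group_id: str) -> tuple[str, ...]:
        return tuple(c for c in self.class_ids if self.group_of[c] == group_id)

    @property
    def all_indicator_ids(self) -> tuple[str, ...]:
        return (
            self.class_ids
            + self.group_ids
            + self.generic_flags
            + self.maintenance_flags
        )

    def variable_sets(self) -> dict[str, tuple[str, ...]]:
        """Column ids for the three candidate variable sets.

        ``full`` is every atomic indicator (classes plus generic and
        maintenance flags); ``groups`` is the parsimonious set (group,
        generic and maintenance indicators only); the screened set is
        selected at fit time from the ``full`` pool.
        """
        full = self.class_ids + self.generic_flags + self.maintenance_flags
        groups = self.group_ids + self.generic_flags + self.maintenance_flags
        return {"full": full, "groups": groups}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "class_ids": list(self.class_ids),
            "group_of": dict(self.group_of),
            "generic_flags": list(self.generic_flags),
            "maintenance_flags": list(self.maintenance_flags),
            "forced_ids": list(self.forced_ids),
            "generic_of": dict(self.generic_of),
            "maintenance_of": dict(self.maintenance_of),
            "excluded_group_indicators": list(self.excluded_group_indicators),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugVocabulary":
        doc = json.loads(Path(path).read_text())
        return cls(
            class_ids=tuple(doc["class_ids"]),
            group_of=doc["group_of"],
            generic_flags=tuple(doc["generic_flags"]),
            maintenance_flags=tuple(doc["maintenance_flags"]),
            forced_ids=tuple(doc["forced_ids"]),
            generic_of=doc["generic_of"],
            maintenance_of=doc["maintenance_of"],
            excluded_group_indicators=tuple(doc.get("excluded_group_indicators", ())),
        )


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a commercial under-65 population: roughly 30% of
    enrollees with no drug use at all, drug-attributable spending under
    ~20% of total spending, heavy right-tailed annual costs with rare
    multi-million-dollar outliers, and a risk score that captures most —
    but not all — of the cost signal of drug classes.

    Monetary quantities are $/year.  ``class_prevalences`` are Bernoulli
    rates *among drug users*; ``class_cost_effects`` are additive expected
    total-cost effects; ``risk_capture`` is the per-class fraction of that
    effect reflected in the risk score (1 = fully risk adjusted).
    """

    n: int = 10_000
    seed: int = 0

    # vocabulary shape
    n_classes: int = 239
    n_groups: int = 31
    n_generic: int = 8
    n_maintenance: int = 5
    n_forced: int = 2

    # drug-use structure
    zero_drug_spend_frac: float = 0.30
    group_correlation: float = 0.4
    group_latent_rate: float = 0.3
    class_prevalences: np.ndarray | None = None

    # cost model
    class_cost_effects: np.ndarray | None = None
    base_positive_rate: float = 0.85
    base_cost_mean: float = 3_800.0
    base_cost_sigma: float = 1.6
    drug_baseline_mean: float = 500.0
    drug_baseline_sigma: float = 1.0
    effect_noise_shape: float = 2.0
    drug_fraction_of_effect: float = 0.3
    outlier_rate: float = 2e-6
    outlier_scale: float = 2.0e6
    outlier_tail: float = 2.5

    # risk-score model
    risk_capture: np.ndarray | float | None = None
    drug_capture: float = 1.0
    risk_noise_sd: float = 1_500.0
    risk_floor: float = 100.0

    # demographics (summary reporting only, never predictors)
    age_mean: float = 42.0
    age_sd: float = 13.0
    female_frac: float = 0.49
    age_cost_slope: float = 40.0
    female_cost_effect: float = 300.0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2 (cohort means are degenerate)")
        if not (0.0 <= self.zero_drug_spend_frac <= 1.0):
            raise ValueError("zero_drug_spend_frac must be in [0, 1]")
        if self.n_groups < 1 or self.n_classes < self.n_groups:
            raise ValueError("need >= 1 group and >= 1 class per group")
        if self.n_forced > self.n_classes:
            raise ValueError("forced class count exceeds class count")
        if self.class_prevalences is not None:
            p = np.asarray(self.class_prevalences, dtype=float)
            if p.shape != (self.n_classes,) or np.any((p < 0) | (p > 1)):
                raise ValueError("class_prevalences must be n_classes rates in [0, 1]")
        cap = self.risk_capture
        if cap is not None and not np.isscalar(cap):
            cap = np.asarray(cap, dtype=float)
            if cap.shape != (self.n_classes,) or np.any((cap < 0) | (cap > 1)):
                raise ValueError("risk_capture must be n_classes fractions in [0, 1]")
        elif np.isscalar(cap) and cap is not None:
            if not (0.0 <= float(cap) <= 1.0):
                raise ValueError("risk_capture must be in [0, 1]")

    # ---- derived defaults -------------------------------------------------

    def resolved_prevalences(self, vocab: DrugVocabulary) -> np.ndarray:
        """Per-class rates among drug users; geometric 0.12 -> 0.002."""
        if self.class_prevalences is not None:
            return np.asarray(self.class_prevalences, dtype=float)
        C = self.n_classes
        i = np.arange(C)
        p = 0.12 * (0.002 / 0.12) ** (i / max(C - 1, 1))
        for cid, rate in ((HIV_CLASS_ID, 0.004), (MS_CLASS_ID, 0.0025)):
            if cid in vocab.class_ids:
                p[vocab.class_ids.index(cid)] = rate
        return p

    def resolved_effects(self, vocab: DrugVocabulary) -> np.ndarray:
        """Per-class $ effects; rarer classes are costlier, HIV/MS largest."""
        if self.class_cost_effects is not None:
            return np.asarray(self.class_cost_effects, dtype=float)
        C = self.n_classes
        i = np.arange(C)
        d = 60.0 * (2_500.0 / 60.0) ** (i / max(C - 1, 1))
        d[[j for j in RESIDUAL_CLASS_INDICES if j < C]] = 3_000.0
        for cid, eff in ((HIV_CLASS_ID, 24_000.0), (MS_CLASS_ID, 42_000.0)):
            if cid in vocab.class_ids:
                d[vocab.class_ids.index(cid)] = eff
        return d

    def resolved_capture(self, vocab: DrugVocabulary) -> np.ndarray:
        """Per-class risk capture; mostly 0.97, residual classes at 0.30."""
        if self.risk_capture is None:
            C = self.n_classes
            cap = np.full(C, 0.97)
            cap[[j for j in RESIDUAL_CLASS_INDICES if j < C]] = 0.30
            for cid in (HIV_CLASS_ID, MS_CLASS_ID):
                if cid in vocab.class_ids:
                    cap[vocab.class_ids.index(cid)] = 0.50
            return cap
        if np.isscalar(self.risk_capture):
            return np.full(self.n_classes, float(self.risk_capture))
        return np.asarray(self.risk_capture, dtype=float)


# --------------------------------------------------------------------------
# enrollee table
# --------------------------------------------------------------------------


@dataclass
class EnrolleeTable:
    """Per-enrollee cohort: cost, risk score, and binary drug indicators.

    ``frame`` columns: ``id``, ``cost``, ``risk_score``, optional
    demographics (``age``, ``female``), then one binary column per
    vocabulary indicator (classes, groups, generic flags, maintenance
    flags, in vocabulary order).
    """

    frame: pd.DataFrame
    vocab: DrugVocabulary

    RESERVED = ("id", "cost", "risk_score", "age", "female")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.vocab.all_indicator_ids if c in self.frame.columns]

    @property
    def X(self) -> pd.DataFrame:
        """View of all indicator columns (the predictor matrix)."""
        return self.frame[self.indicator_columns]

    @property
    def costs(self) -> np.ndarray:
        return self.frame["cost"].to_numpy(dtype=float)

    @property
    def risk_scores(self) -> np.ndarray:
        return self.frame["risk_score"].to_numpy(dtype=float)

    def validate(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("cohort contains missing values")
        if np.any(self.costs < 0):
            raise ValueError("negative costs")
        if np.any(self.risk_scores <= 0):
            raise ValueError("non-positive risk scores")
        ind = self.X.to_numpy()
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator values must be 0/1")
        # group = OR of member classes, where both sides are present
        for g in self.vocab.group_ids:
            if g not in self.frame.columns:
                continue
            members = [c for c in self.vocab.classes_in_group(g) if c in self.frame.columns]
            if members:
                expected = self.frame[members].to_numpy().max(axis=1)
                if not np.array_equal(expected, self.frame[g].to_numpy()):
                    raise ValueError(f"group indicator {g} is not the OR of its classes")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_vocabulary(config: CohortConfig) -> DrugVocabulary:
    """Build the drug-variable hierarchy from the config's shape fields.

    Classes are split over groups in contiguous blocks whose sizes differ
    by at most one (default 239 classes over 31 groups).  Two classes are
    designated forced: HIV antivirals and MS biologicals.  Construction is
    deterministic: the same config always yields the same vocabulary.
    """
    config.validate()
    C, G = config.n_classes, config.n_groups

    class_ids = [f"tc_{i + 1:03d}" for i in range(C)]
    forced: list[str] = []
    if config.n_forced >= 1:
        idx_hiv = min(40, C - 1)
        class_ids[idx_hiv] = HIV_CLASS_ID
        forced.append(HIV_CLASS_ID)
    if config.n_forced >= 2:
        idx_ms = min(120, C - 2)
        if class_ids[idx_ms] == HIV_CLASS_ID:
            idx_ms += 1
        class_ids[idx_ms] = MS_CLASS_ID
        forced.append(MS_CLASS_ID)
    if config.n_forced > 2:
        raise ValueError("at most two forced classes are defined")

    group_ids = [f"tg_{g + 1:02d}" for g in range(G)]
    base, rem = divmod(C, G)
    sizes = [base + 1] * rem + [base] * (G - rem)
    group_of: dict[str, str] = {}
    pos = 0
    for gid, size in zip(group_ids, sizes):
        for c in class_ids[pos : pos + size]:
            group_of[c] = gid
        pos += size

    generic = GENERIC_FLAG_IDS[: config.n_generic]
    maint = MAINTENANCE_FLAG_IDS[: config.n_maintenance]
    generic_of = {c: generic[i % len(generic)] for i, c in enumerate(class_ids)}
    maintenance_of = {c: maint[i % len(maint)] for i, c in enumerate(class_ids)}

    return DrugVocabulary(
        class_ids=tuple(class_ids),
        group_of=group_of,
        generic_flags=tuple(generic),
        maintenance_flags=tuple(maint),
        forced_ids=tuple(forced),
        generic_of=generic_of,
        maintenance_of=maintenance_of,
    )


def generate_cohort(
    vocab: DrugVocabulary,
    config: CohortConfig,
    return_components: bool = False,
) -> EnrolleeTable | tuple[EnrolleeTable, pd.DataFrame]:
    """Draw a cohort of ``config.n`` enrollees.

    Mechanism, per enrollee:

    1. ``drug_user ~ Bernoulli(1 - zero_drug_spend_frac)``; non-users have
       an all-zero indicator vector and no drug spending.
    2. Per group a latent condition ``L_g ~ Bernoulli(group_latent_rate)``;
       class ``c`` in group ``g`` fires with probability
       ``p_c * (1 - rho + rho * L_g / group_latent_rate)`` for drug users,
       which preserves the marginal rate ``p_c`` while inducing positive
       within-group correlation of strength ``rho``.
    3. Cost = zero-inflated lognormal base (demographics shift its mean)
       + drug-user baseline + sum of class effects with Gamma(mean 1)
       multiplicative noise + a rare Pareto outlier.
    4. Risk index = expected base cost + captured drug-user baseline
       + sum of capture-attenuated class effects + the outlier mean
       + Gaussian noise; floored at ``risk_floor`` and rescaled to mean 1.

    With ``return_components=True`` a second frame carries per-enrollee
    generator internals (expected cost given the drawn indicators, the
    noiseless risk index, drug-attributable spending) for oracle checks.
    """
    config.validate()
    n, C = config.n, config.n_classes
    prev = config.resolved_prevalences(vocab)
    delta = config.resolved_effects(vocab)
    kappa = config.resolved_capture(vocab)
    rho = config.group_correlation
    g_rate = config.group_latent_rate

    rng_demo = substream(config.seed, "cohort", "demographics")
    rng_use = substream(config.seed, "cohort", "drug_user")
    rng_lat = substream(config.seed, "cohort", "group_latents")
    rng_cls = substream(config.seed, "cohort", "classes")
    rng_base = substream(config.seed, "cohort", "base_cost")
    rng_drug = substream(config.seed, "cohort", "drug_base")
    rng_eff = substream(config.seed, "cohort", "effect_noise")
    rng_out = substream(config.seed, "cohort", "outliers")
    rng_risk = substream(config.seed, "cohort", "risk_noise")

    age = np.clip(rng_demo.normal(config.age_mean, config.age_sd, n), 18, 64)
    female = (rng_demo.random(n) < config.female_frac).astype(np.int8)

    drug_user = (rng_use.random(n) < 1.0 - config.zero_drug_spend_frac).astype(np.int8)

    group_ids = vocab.group_ids
    group_index = {g: i for i, g in enumerate(group_ids)}
    latents = (rng_lat.random((n, len(group_ids))) < g_rate).astype(np.int8)

    class_group = np.array([group_index[vocab.group_of[c]] for c in vocab.class_ids])
    # conditional firing probability given the group latent
    lam = latents[:, class_group]  # n x C
    prob = prev[None, :] * (1.0 - rho + rho * lam / g_rate)
    np.clip(prob, 0.0, 1.0, out=prob)
    X = ((rng_cls.random((n, C)) < prob) & (drug_user[:, None] == 1)).astype(np.int8)

    # base (non-drug) cost: zero-inflated lognormal, demographic mean shift
    base_mean = (
        config.base_cost_mean
        + config.age_cost_slope * (age - config.age_mean)
        + config.female_cost_effect * female
    )
    base_mean = np.maximum(base_mean, 100.0)
    sigma = config.base_cost_sigma
    mu = np.log(base_mean) - 0.5 * sigma**2
    base_pos = (rng_base.random(n) < config.base_positive_rate).astype(float)
    base = base_pos * rng_base.lognormal(mu, sigma)

    # drug-user baseline spending
    mu_d = np.log(config.drug_baseline_mean) - 0.5 * config.drug_baseline_sigma**2
    drug_base = drug_user * rng_drug.lognormal(mu_d, config.drug_baseline_sigma, n)

    # class effects with mean-one gamma noise
    shape = config.effect_noise_shape
    noise = rng_eff.gamma(shape, 1.0 / shape, size=(n, C))
    effect_draw = X * (delta[None, :] * noise)
    effects = effect_draw.sum(axis=1)

    # rare catastrophic outliers (Pareto tail, minimum outlier_scale)
    is_outlier = rng_out.random(n) < config.outlier_rate
    outlier = np.where(
        is_outlier, config.outlier_scale * (1.0 + rng_out.pareto(config.outlier_tail, n)), 0.0
    )
    outlier_mean = (
        config.outlier_rate * config.outlier_scale * config.outlier_tail / (config.outlier_tail - 1.0)
    )

    cost = base + drug_base + effects + outlier

    # risk index on the $ scale, then floored and rescaled to mean 1
    expected_base = config.base_positive_rate * base_mean
    risk_index = (
        expected_base
        + drug_user * config.drug_baseline_mean * config.drug_capture
        + X @ (kappa * delta)
        + outlier_mean
    )
    s_raw = np.maximum(
        config.risk_floor, risk_index + rng_risk.normal(0.0, config.risk_noise_sd, n)
    )
    risk_score = s_raw / s_raw.mean()

    frame = pd.DataFrame({"id": np.arange(n), "cost": cost, "risk_score": risk_score})
    frame["age"] = np.round(age).astype(int)
    frame["female"] = female

    ind = pd.DataFrame(X, columns=list(vocab.class_ids))
    for g in group_ids:
        members = list(vocab.classes_in_group(g))
        ind[g] = ind[members].to_numpy().max(axis=1)
    for flag, mapping in (
        (vocab.generic_flags, vocab.generic_of),
        (vocab.maintenance_flags, vocab.maintenance_of),
    ):
        for f in flag:
            members = [c for c in vocab.class_ids if mapping[c] == f]
            ind[f] = ind[members].to_numpy().max(axis=1) if members else 0
    frame = pd.concat([frame, ind.astype(np.int8)], axis=1)

    table = EnrolleeTable(frame=frame, vocab=vocab)
    if not return_components:
        return table

    expected_cost = (
        expected_base + drug_user * config.drug_baseline_mean + X @ delta + outlier_mean
    )
    drug_spend = drug_base + config.drug_fraction_of_effect * effects
    components = pd.DataFrame(
        {
            "drug_user": drug_user,
            "expected_cost": expected_cost,
            "risk_index": risk_index,
            "drug_spend": drug_spend,
            "outlier": is_outlier.astype(int),
        }
    )
    return table, components


# --------------------------------------------------------------------------
# variable filtering
# --------------------------------------------------------------------------


def drop_empty_variables(table: EnrolleeTable) -> EnrolleeTable:
    """Drop indicators with no positive claims and singleton-group columns.

    Mirrors the study's data preparation: indicator columns that are zero
    for every enrollee are removed, and a group indicator that aggregates a
    single surviving class is removed as a duplicate of that class.  The
    vocabulary is rewritten to match the surviving columns.
    """
    frame = table.frame
    vocab = table.vocab
    counts = {c: int(frame[c].sum()) for c in table.indicator_columns}

    surviving_classes = [c for c in vocab.class_ids if counts.get(c, 0) > 0]
    if not surviving_classes:
        warnings.warn("all indicator columns are empty; returning a bare table")

    dropped_forced = [f for f in vocab.forced_ids if f not in surviving_classes]
    if dropped_forced:
        warnings.warn(f"forced classes with no positive claims dropped: {dropped_forced}")

    new_group_of = {c: vocab.group_of[c] for c in surviving_classes}
    member_count: dict[str, int] = {}
    for c in surviving_classes:
        member_count[new_group_of[c]] = member_count.get(new_group_of[c], 0) + 1
    excluded_groups = tuple(
        g
        for g in dict.fromkeys(new_group_of.values())
        if member_count.get(g, 0) < 2 or counts.get(g, 0) == 0
    )
    surviving_generic = [f for f in vocab.generic_flags if counts.get(f, 0) > 0]
    surviving_maint = [f for f in vocab.maintenance_flags if counts.get(f, 0) > 0]

    new_vocab = DrugVocabulary(
        class_ids=tuple(surviving_classes),
        group_of=new_group_of,
        generic_flags=tuple(surviving_generic),
        maintenance_flags=tuple(surviving_maint),
        forced_ids=tuple(f for f in vocab.forced_ids if f in surviving_classes),
        generic_of={c: vocab.generic_of[c] for c in surviving_classes},
        maintenance_of={c: vocab.maintenance_of[c] for c in surviving_classes},
        excluded_group_indicators=excluded_groups,
    )
    keep = [c for c in frame.columns if c in EnrolleeTable.RESERVED]
    keep += [c for c in new_vocab.all_indicator_ids if c in frame.columns]
    # group columns removed from the vocabulary's group set are dropped even
    # though their member class survives
    return EnrolleeTable(frame=frame[keep].copy(), vocab=new_vocab)


# --------------------------------------------------------------------------
# I/O and summary
# --------------------------------------------------------------------------


def save_cohort(table: EnrolleeTable, path: str | Path) -> None:
    """Write the cohort CSV (header: id, cost, risk_score, [age, female], indicators)."""
    table.frame.to_csv(path, index=False)


def load_cohort(path: str | Path, vocab: DrugVocabulary) -> EnrolleeTable:
    """Read and validate a cohort CSV against a vocabulary.

    Raises ``ValueError`` naming the offending column or row for missing or
    extra columns, negative costs, and non-binary indicators.
    """
    frame = pd.read_csv(path)
    required = ["id", "cost", "risk_score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    expected = set(required) | {"age", "female"} | set(vocab.all_indicator_ids)
    extra = [c for c in frame.columns if c not in expected]
    if extra:
        raise ValueError(f"cohort file has unexpected columns: {extra}")
    missing_ind = [c for c in vocab.all_indicator_ids if c not in frame.columns]
    if missing_ind:
        raise ValueError(f"cohort file missing indicator columns: {missing_ind[:5]}")
    neg = np.flatnonzero(frame["cost"].to_numpy() < 0)
    if neg.size:
        raise ValueError(f"negative cost at row {int(neg[0])}")
    for c in vocab.all_indicator_ids:
        vals = frame[c].to_numpy()
        bad = np.flatnonzero(~np.isin(vals, (0, 1)))
        if bad.size:
            raise ValueError(f"non-binary indicator value in column {c} at row {int(bad[0])}")
    table = EnrolleeTable(frame=frame, vocab=vocab)
    table.validate()
    return table


def cohort_summary(table: EnrolleeTable) -> dict:
    """Headline summary facts: size, cost moments, zero-drug-use fraction."""
    class_cols = [c for c in table.vocab.class_ids if c in table.frame.columns]
    any_drug = table.frame[class_cols].to_numpy().max(axis=1) if class_cols else np.zeros(table.n)
    return {
        "n": table.n,
        "mean_cost": float(np.mean(table.costs)),
        "sd_cost": float(np.std(table.costs)),
        "median_cost": float(np.median(table.costs)),
        "zero_drug_use_frac": float(1.0 - np.mean(any_drug)),
        "mean_risk_score": float(np.mean(table.risk_scores)),
        "mean_age": float(table.frame["age"].mean()) if "age" in table.frame else None,
        "female_frac": float(table.frame["female"].mean()) if "female" in table.frame else None,
        "n_indicators": len(table.indicator_columns),
    }
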