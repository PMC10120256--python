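"""Stage 2: ratio-of-odds-ratios (ROR) contrasts across reviews.

Each eligible review contributes one ROR: its trials are split into two
strata (by publication language, target population, or a risk-of-bias
rating), each stratum is pooled with the model/method/correction the
review itself reported, and the ROR is the ratio of the two pooled odds
ratios.  On the log scale the ROR variance is the sum of the two stratum
variances (the strata are disjoint trial sets).  Review-level RORs are
then pooled across reviews with a random-effects inverse-variance model
(DerSimonian-Laird between-review variance).

A pooled ROR is interpreted through its 95% confidence interval: entirely
below 1 means the first stratum (e.g. Chinese-language trials) shows the
larger treatment effect under the OR < 1 = benefit convention; entirely
above 1 means the second stratum does; an interval containing 1 is
inconclusive.

Four preset designs are provided:

* ``language_overall`` — Chinese- vs non-Chinese-language trials, one ROR
  per review, pooled overall and by outcome role (primary vs secondary);
* ``rob_within_language`` — within each language stratum, for each ROB
  domain, trials rated high/unclear vs low on that domain;
* ``language_within_high_rob`` — among trials rated high/unclear on each
  domain, Chinese- vs non-Chinese-language trials;
* ``population_low_rob_only`` — among trials rated low on each domain,
  Chinese vs non-Chinese study populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_model import (
    LANGUAGES,
    ROB_DOMAINS,
    ReviewDataset,
    TrialRecord,
    ValidationError,
)
from .meta import (
    EffectEstimate,
    EmptyAnalysisError,
    MetaResult,
    SubgroupComparison,
    ZeroCellError,
    invert_direction,
    pool_inverse_variance,
    pool_trials,
    subgroup_difference,
)
from .selection import select_config

__all__ = [
    "PRESETS",
    "EmptyStratumError",
    "StratificationSpec",
    "RORRecord",
    "PooledROR",
    "ReportRow",
    "AnalysisReport",
    "interpret_ror",
    "stratify",
    "review_ror",
    "pool_rors",
    "pool_rors_by_role",
    "run_analysis_preset",
]

PRESETS: tuple[str, ...] = (
    "language_overall",
    "rob_within_language",
    "language_within_high_rob",
    "population_low_rob_only",
)

_AXES = ("language", "population", "rob_rating")
_HIGH_UNCLEAR = ("high", "unclear")


class EmptyStratumError(ValueError):
    """One side of a stratification is empty; the review is not eligible."""


@dataclass(frozen=True)
class StratificationSpec:
    """How to split one review's trials into the two contrast groups.

    ``axis`` names the contrast: ``language`` (a = chinese, b = other),
    ``population`` (a = chinese, b = non_chinese), or ``rob_rating``
    (a = high/unclear, b = low, on ``rob_domain``).  ``restrict_language``
    keeps only trials in one language before splitting;
    ``restrict_rob = (domain, 'low' | 'high_unclear')`` keeps only trials
    with that rating pattern on the named domain.
    """

    axis: str
    rob_domain: str | None = None
    restrict_language: str | None = None
    restrict_rob: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValidationError(f"unknown stratification axis {self.axis!r}")
        if self.axis == "rob_rating" and self.rob_domain is None:
            raise ValidationError("axis='rob_rating' requires rob_domain")
        if self.rob_domain is not None and self.rob_domain not in ROB_DOMAINS:
            raise ValidationError(f"unknown ROB domain {self.rob_domain!r}")
        if self.restrict_language is not None and self.restrict_language not in LANGUAGES:
            raise ValidationError(f"unknown language {self.restrict_language!r}")
        if self.restrict_rob is not None:
            domain, rating = self.restrict_rob
            if domain not in ROB_DOMAINS:
                raise ValidationError(f"unknown ROB domain {domain!r}")
            if rating not in ("low", "high_unclear"):
                raise ValidationError(
                    f"restrict_rob rating must be 'low' or 'high_unclear'; got {rating!r}"
                )


@dataclass(frozen=True)
class RORRecord:
    """One review's log ROR with provenance and per-stratum bookkeeping."""

    review_id: str
    outcome_name: str
    outcome_role: str
    log_ror: float
    se_log_ror: float
    or_a: float
    or_b: float
    k_a: int
    k_b: int
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (self.se_log_ror > 0 and math.isfinite(self.se_log_ror)):
            raise ValidationError(
                f"review {self.review_id!r}: se_log_ror must be positive"
            )
        if abs(self.log_ror - (math.log(self.or_a) - math.log(self.or_b))) > 1e-9:
            raise ValidationError(
                f"review {self.review_id!r}: log_ror inconsistent with or_a/or_b"
            )

    @property
    def ror(self) -> float:
        return math.exp(self.log_ror)


@dataclass(frozen=True)
class PooledROR:
    """An across-review random-effects pooled ROR with its reading."""

    ror: float
    ci_low: float
    ci_high: float
    k_reviews: int
    tau2: float
    i2_percent: float
    interpretation: str
    log_ror: float
    se: float


def interpret_ror(ci_low: float, ci_high: float) -> str:
    """Read a pooled ROR from its 95% CI.

    Entirely below 1: the first stratum shows the larger effect;
    entirely above 1: the second does; an interval containing 1 is
    inconclusive.
    """
    if ci_high < 1.0:
        return "group_a_larger_effect"
    if ci_low > 1.0:
        return "group_b_larger_effect"
    return "inconclusive"


def _passes(trial: TrialRecord, spec: StratificationSpec) -> bool:
    if spec.restrict_language is not None and trial.language != spec.restrict_language:
        return False
    if spec.restrict_rob is not None:
        domain, rating = spec.restrict_rob
        if rating == "low" and trial.rob[domain] != "low":
            return False
        if rating == "high_unclear" and trial.rob[domain] not in _HIGH_UNCLEAR:
            return False
    return True


def stratify(
    trials: Sequence[TrialRecord], spec: StratificationSpec
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Partition one review's trials into the two contrast groups.

    Raises :class:`EmptyStratumError` when either group is empty after
    applying any restriction, signalling that the review contributes no
    ROR to this analysis.
    """
    eligible = [t for t in trials if _passes(t, spec)]
    if spec.axis == "language":
        group_a = [t for t in eligible if t.language == "chinese"]
        group_b = [t for t in eligible if t.language == "other"]
    elif spec.axis == "population":
        group_a = [t for t in eligible if t.population == "chinese"]
        group_b = [t for t in eligible if t.population == "non_chinese"]
    else:
        domain = spec.rob_domain
        group_a = [t for t in eligible if t.rob[domain] in _HIGH_UNCLEAR]
        group_b = [t for t in eligible if t.rob[domain] == "low"]
    if not group_a or not group_b:
        raise EmptyStratumError(
            f"stratification on {spec.axis!r} leaves an empty group "
            f"(sizes {len(group_a)} vs {len(group_b)})"
        )
    return group_a, group_b


def review_ror(
    meta_a: MetaResult,
    meta_b: MetaResult,
    *,
    outcome_name: str = "",
    outcome_role: str = "primary",
) -> RORRecord:
    """Combine two stratum results of one review into its ROR.

    log ROR = log OR_a - log OR_b; its variance is the sum of the two
    stratum variances.
    """
    if meta_a.review_id != meta_b.review_id:
        raise ValidationError(
            f"stratum results belong to different reviews: "
            f"{meta_a.review_id!r} vs {meta_b.review_id!r}"
        )
    return RORRecord(
        review_id=meta_a.review_id or "",
        outcome_name=outcome_name,
        outcome_role=outcome_role,
        log_ror=meta_a.pooled_log_or - meta_b.pooled_log_or,
        se_log_ror=math.hypot(meta_a.se, meta_b.se),
        or_a=meta_a.or_point,
        or_b=meta_b.or_point,
        k_a=meta_a.k,
        k_b=meta_b.k,
        n_a=meta_a.n_participants or 0,
        n_b=meta_b.n_participants or 0,
    )


def _records_to_meta(records: Sequence[RORRecord]) -> MetaResult:
    effects = [
        EffectEstimate(trial_id=r.review_id, log_or=r.log_ror, se=r.se_log_ror)
        for r in records
    ]
    return pool_inverse_variance(effects, model="random")


def pool_rors(records: Sequence[RORRecord]) -> PooledROR:
    """Random-effects inverse-variance pooling of review-level log RORs."""
    if not records:
        raise EmptyAnalysisError("no ROR records to pool")
    meta = _records_to_meta(records)
    return PooledROR(
        ror=meta.or_point,
        ci_low=meta.ci_low,
        ci_high=meta.ci_high,
        k_reviews=meta.k,
        tau2=meta.tau2,
        i2_percent=meta.i2_percent,
        interpretation=interpret_ror(meta.ci_low, meta.ci_high),
        log_ror=meta.pooled_log_or,
        se=meta.se,
    )


def pool_rors_by_role(
    records: Sequence[RORRecord],
) -> tuple[dict[str, PooledROR], SubgroupComparison | None]:
    """Pooled RORs per outcome role plus the between-role difference test.

    The comparison is None when only one role is present.
    """
    if not records:
        raise EmptyAnalysisError("no ROR records to pool")
    by_role: dict[str, PooledROR] = {}
    metas: list[MetaResult] = []
    for role in ("primary", "secondary"):
        subset = [r for r in records if r.outcome_role == role]
        if subset:
            by_role[role] = pool_rors(subset)
            metas.append(_records_to_meta(subset))
    comparison = subgroup_difference(metas) if len(metas) >= 2 else None
    return by_role, comparison


@dataclass(frozen=True)
class ReportRow:
    """One analysis row: a stratification design applied across reviews."""

    preset: str
    stratum: str
    rob_domain: str
    records: tuple[RORRecord, ...]
    pooled: PooledROR | None

    @property
    def k_reviews(self) -> int:
        return len(self.records)

    @property
    def k_trials_a(self) -> int:
        return sum(r.k_a for r in self.records)

    @property
    def k_trials_b(self) -> int:
        return sum(r.k_b for r in self.records)

    @property
    def n_a(self) -> int:
        return sum(r.n_a for r in self.records)

    @property
    def n_b(self) -> int:
        return sum(r.n_b for r in self.records)


@dataclass(frozen=True)
class AnalysisReport:
    """The rows of one preset plus exclusion log and optional role contrast."""

    preset: str
    rows: tuple[ReportRow, ...]
    log: tuple[str, ...] = ()
    by_role: dict[str, PooledROR] | None = None
    role_comparison: SubgroupComparison | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat table of the report rows (raw floats; formatting is the CLI's)."""
        out = []
        for row in self.rows:
            pooled = row.pooled
            out.append(
                {
                    "preset": row.preset,
                    "stratum": row.stratum,
                    "rob_domain": row.rob_domain,
                    "k_reviews": row.k_reviews,
                    "k_trials_a": row.k_trials_a,
                    "k_trials_b": row.k_trials_b,
                    "n_a": row.n_a,
                    "n_b": row.n_b,
                    "ror": pooled.ror if pooled else float("nan"),
                    "ci_low": pooled.ci_low if pooled else float("nan"),
                    "ci_high": pooled.ci_high if pooled else float("nan"),
                    "tau2": pooled.tau2 if pooled else float("nan"),
                    "i2_percent": pooled.i2_percent if pooled else float("nan"),
                    "interpretation": pooled.interpretation if pooled else "no_data",
                }
            )
        return pd.DataFrame(out)


def _ror_for_review(
    dataset: ReviewDataset,
    review_id: str,
    spec: StratificationSpec,
    log: list[str],
) -> RORRecord | None:
    config = select_config(dataset, review_id)
    if config is None:
        log.append(f"review {review_id}: no eligible outcome (excluded)")
        return None
    trials = dataset.trials_for(review_id)
    try:
        group_a, group_b = stratify(trials, spec)
    except EmptyStratumError as err:
        log.append(f"review {review_id}: {err}")
        return None
    try:
        meta_a = pool_trials(group_a, config, review_id=review_id)
        meta_b = pool_trials(group_b, config, review_id=review_id)
    except (EmptyAnalysisError, ZeroCellError) as err:
        log.append(f"review {review_id}: {err}")
        return None
    if config.invert_direction:
        meta_a = invert_direction(meta_a)
        meta_b = invert_direction(meta_b)
    for meta in (meta_a, meta_b):
        if meta.excluded_trials:
            log.append(
                f"review {review_id}: excluded no-information trials "
                f"{', '.join(meta.excluded_trials)}"
            )
    return review_ror(
        meta_a,
        meta_b,
        outcome_name=config.outcome_name,
        outcome_role=config.outcome_role,
    )


def _collect(
    dataset: ReviewDataset, spec: StratificationSpec, log: list[str]
) -> list[RORRecord]:
    records = []
    for review_id in dataset.review_ids:
        if not dataset.trials_for(review_id):
            continue
        record = _ror_for_review(dataset, review_id, spec, log)
        if record is not None:
            records.append(record)
    return records


def run_analysis_preset(dataset: ReviewDataset, preset: str) -> AnalysisReport:
    """Run one of the four preset stratification designs over a dataset.

    Every report row carries the number of contributing reviews, trial
    and participant counts per stratum, the pooled ROR with its 95% CI
    and heterogeneity, and the CI-based interpretation; reviews that
    lack a stratum are logged and skipped.  The ``language_overall``
    preset additionally pools primary and secondary outcomes separately
    and tests the difference between the two roles.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    log: list[str] = []
    rows: list[ReportRow] = []
    by_role = None
    role_comparison = None

    if preset == "language_overall":
        spec = StratificationSpec(axis="language")
        records = _collect(dataset, spec, log)
        pooled = pool_rors(records) if records else None
        rows.append(
            ReportRow(preset, "overall", "", tuple(records), pooled)
        )
        if records:
            by_role, role_comparison = pool_rors_by_role(records)
            for role, pooled_role in by_role.items():
                role_records = tuple(r for r in records if r.outcome_role == role)
                rows.append(ReportRow(preset, role, "", role_records, pooled_role))
    elif preset == "rob_within_language":
        for language in LANGUAGES:
            for domain in ROB_DOMAINS:
                spec = StratificationSpec(
                    axis="rob_rating", rob_domain=domain, restrict_language=language
                )
                records = _collect(dataset, spec, log)
                pooled = pool_rors(records) if records else None
                if not records:
                    log.append(
                        f"{language}/{domain}: no review has both ROB strata"
                    )
                rows.append(
                    ReportRow(preset, language, domain, tuple(records), pooled)
                )
    elif preset == "language_within_high_rob":
        for domain in ROB_DOMAINS:
            spec = StratificationSpec(
                axis="language", restrict_rob=(domain, "high_unclear")
            )
            records = _collect(dataset, spec, log)
            pooled = pool_rors(records) if records else None
            if not records:
                log.append(f"high_unclear/{domain}: no eligible review")
            rows.append(
                ReportRow(preset, "high_unclear_risk", domain, tuple(records), pooled)
            )
    else:  # population_low_rob_only
        for domain in ROB_DOMAINS:
            spec = StratificationSpec(
                axis="population", restrict_rob=(domain, "low")
            )
            records = _collect(dataset, spec, log)
            pooled = pool_rors(records) if records else None
            if not records:
                log.append(f"low_risk/{domain}: no eligible review")
            rows.append(
                ReportRow(preset, "low_risk", domain, tuple(records), pooled)
            )

    return AnalysisReport(
        preset=preset,
        rows=tuple(rows),
        log=tuple(log),
        by_role=by_role,
        role_comparison=role_comparison,
    )
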