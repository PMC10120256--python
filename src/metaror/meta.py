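"""Within-review meta-analysis of 2x2 tables.

Implements the standard binary-outcome toolkit on the natural-log
odds-ratio scale:

* per-trial log OR and its large-sample standard error, with a 0.5
  continuity correction for tables containing a zero cell;
* fixed-effect inverse-variance pooling and DerSimonian-Laird
  random-effects pooling;
* Mantel-Haenszel fixed-effect pooling with the
  Robins-Breslow-Greenland variance for ln(OR_MH);
* Cochran's Q, I^2 (with the conventional overlapping descriptive
  bands), and the between-subgroup chi-square test.

Trials with no information about the odds ratio (zero events in both
arms, or all events in both arms) are excluded rather than corrected,
matching common systematic-review practice.  95% confidence intervals
use the normal quantile 1.96 on the log scale.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import OutcomeConfig, TrialRecord, ValidationError

__all__ = [
    "Z95",
    "I2_BANDS",
    "ZeroCellError",
    "EmptyAnalysisError",
    "EffectEstimate",
    "MetaResult",
    "SubgroupComparison",
    "trial_effect",
    "trial_effects",
    "pool_inverse_variance",
    "pool_mantel_haenszel",
    "pool_trials",
    "dersimonian_laird",
    "heterogeneity",
    "subgroup_difference",
    "invert_direction",
]

logger = logging.getLogger(__name__)

#: Normal quantile used for 95% confidence intervals on the log scale.
Z95 = 1.96

#: Descriptive I^2 bands; the ranges deliberately overlap, so a value can
#: fall in more than one band (inclusive at both ends).
I2_BANDS: dict[str, tuple[float, float]] = {
    "not_important": (0.0, 40.0),
    "moderate": (30.0, 60.0),
    "substantial": (50.0, 90.0),
    "considerable": (75.0, 100.0),
}


class ZeroCellError(ValueError):
    """A 2x2 table has a zero cell but the configuration forbids correction."""


class EmptyAnalysisError(ValueError):
    """No trial contributes information to the requested pooling."""


@dataclass(frozen=True)
class EffectEstimate:
    """A per-trial log odds ratio with its standard error."""

    trial_id: str
    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValidationError(f"trial {self.trial_id!r}: log_or is not finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"trial {self.trial_id!r}: se must be positive")


@dataclass(frozen=True)
class MetaResult:
    """A pooled odds ratio with heterogeneity diagnostics.

    ``pooled_log_or`` and ``se`` live on the natural-log scale;
    ``or_point``, ``ci_low`` and ``ci_high`` are the exponentiated
    point estimate and 95% interval.  ``q``/``df``/``p_q`` are
    Cochran's heterogeneity test; ``tau2`` is the between-trial
    variance (0 under a fixed-effect model) and ``i2_percent`` the
    derived inconsistency percentage with its descriptive bands.
    """

    k: int
    pooled_log_or: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    p_q: float
    tau2: float
    i2_percent: float
    i2_bands: tuple[str, ...]
    model: str
    method: str
    excluded_trials: tuple[str, ...] = ()
    review_id: str | None = None
    n_participants: int | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.ci_low <= self.or_point * (1 + eps) and
                self.or_point <= self.ci_high * (1 + eps)):
            raise ValidationError("confidence interval does not bracket the estimate")
        if self.model == "fixed" and self.tau2 != 0.0:
            raise ValidationError("fixed-effect result must have tau2 = 0")
        if self.q <= self.df and self.i2_percent != 0.0:
            raise ValidationError("i2 must be 0 when q <= df")
        if not 0.0 <= self.i2_percent <= 100.0:
            raise ValidationError("i2 out of [0, 100]")


@dataclass(frozen=True)
class SubgroupComparison:
    """Between-subgroup heterogeneity test (chi-square on pooled effects)."""

    q_between: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        """Significant at the conventional P < 0.05 threshold."""
        return self.p_value < 0.05


def _cells(
    trial: TrialRecord, correction: str
) -> tuple[float, float, float, float, bool] | None:
    """Return (a, b, c, d, corrected) or None for a no-information table."""
    a = float(trial.events_treat)
    b = float(trial.n_treat - trial.events_treat)
    c = float(trial.events_ctrl)
    d = float(trial.n_ctrl - trial.events_ctrl)
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return None
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise ZeroCellError(
                f"trial {trial.trial_id!r} in review {trial.review_id!r} has a zero "
                "cell and continuity_correction='none': log odds ratio undefined"
            )
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def trial_effect(
    trial: TrialRecord, correction: str = "constant_half"
) -> EffectEstimate | None:
    """Per-trial log odds ratio, or None if the trial carries no information.

    With cells a, b, c, d (events / non-events per arm),
    log OR = ln(ad / bc) and SE = sqrt(1/a + 1/b + 1/c + 1/d).  If any
    cell is zero and ``correction == 'constant_half'``, 0.5 is added to
    all four cells first.  Double-zero and double-all-event tables are
    excluded (return None).
    """
    cells = _cells(trial, correction)
    if cells is None:
        return None
    a, b, c, d, corrected = cells
    return EffectEstimate(
        trial_id=trial.trial_id,
        log_or=math.log(a * d / (b * c)),
        se=math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
        corrected=corrected,
    )


def trial_effects(
    trials: Sequence[TrialRecord], correction: str = "constant_half"
) -> tuple[list[EffectEstimate], list[str]]:
    """Effects for every informative trial plus the ids of excluded ones."""
    effects: list[EffectEstimate] = []
    excluded: list[str] = []
    for trial in trials:
        eff = trial_effect(trial, correction)
        if eff is None:
            excluded.append(trial.trial_id)
        else:
            effects.append(eff)
    return effects, excluded


def dersimonian_laird(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimator of the between-trial variance.

    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w)) with
    fixed-effect weights w = 1/se^2.  Returns 0 (with a warning) for
    fewer than two effects.
    """
    k = len(effects)
    if k < 2:
        logger.warning("DerSimonian-Laird needs k >= 2 effects; returning tau2 = 0")
        return 0.0
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    mu = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mu) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def heterogeneity(q: float, df: int) -> tuple[float, tuple[str, ...], float]:
    """I^2 percentage, descriptive bands, and the Q-test p-value.

    I^2 = max(0, (Q - df) / Q) * 100 (defined as 0 when Q = 0); the
    p-value is the upper chi-square tail at ``df`` degrees of freedom
    (1 when df = 0).  The bands overlap, so more than one may apply.
    """
    if q < 0:
        raise ValidationError(f"Q statistic must be non-negative; got {q}")
    if df < 0:
        raise ValidationError(f"degrees of freedom must be non-negative; got {df}")
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    p_q = 1.0 if df == 0 else float(stats.chi2.sf(q, df))
    bands = tuple(
        name for name, (low, high) in I2_BANDS.items() if low <= i2 <= high
    )
    return i2, bands, p_q


def _finish(
    *,
    effects: Sequence[EffectEstimate],
    pooled: float,
    se: float,
    q: float,
    df: int,
    tau2: float,
    model: str,
    method: str,
    excluded: Sequence[str],
    review_id: str | None,
    n_participants: int | None,
) -> MetaResult:
    i2, bands, p_q = heterogeneity(q, df)
    return MetaResult(
        k=len(effects),
        pooled_log_or=pooled,
        se=se,
        or_point=math.exp(pooled),
        ci_low=math.exp(pooled - Z95 * se),
        ci_high=math.exp(pooled + Z95 * se),
        q=q,
        df=df,
        p_q=p_q,
        tau2=tau2,
        i2_percent=i2,
        i2_bands=bands,
        model=model,
        method=method,
        excluded_trials=tuple(excluded),
        review_id=review_id,
        n_participants=n_participants,
    )


def pool_inverse_variance(
    effects: Sequence[EffectEstimate],
    model: str = "fixed",
    *,
    excluded: Sequence[str] = (),
    review_id: str | None = None,
    n_participants: int | None = None,
) -> MetaResult:
    """Inverse-variance pooling of log odds ratios.

    Fixed: weights 1/se_i^2.  Random: DerSimonian-Laird tau^2 added to
    each variance before re-weighting.  Q and I^2 are always computed
    about the fixed-effect mean with fixed-effect weights.
    """
    if model not in ("fixed", "random"):
        raise ValidationError(f"model must be 'fixed' or 'random'; got {model!r}")
    if not effects:
        raise EmptyAnalysisError("no effects to pool")
    theta = np.array([e.log_or for e in effects])
    var = np.array([e.se**2 for e in effects])
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(var))):
        raise ValidationError("non-finite effect or variance in pooling input")
    w = 1.0 / var
    mu_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mu_fixed) ** 2))
    df = len(effects) - 1
    if model == "fixed":
        tau2 = 0.0
        pooled, se = mu_fixed, float(1.0 / math.sqrt(np.sum(w)))
    else:
        tau2 = dersimonian_laird(effects)
        w_r = 1.0 / (var + tau2)
        pooled = float(np.sum(w_r * theta) / np.sum(w_r))
        se = float(1.0 / math.sqrt(np.sum(w_r)))
    return _finish(
        effects=effects, pooled=pooled, se=se, q=q, df=df, tau2=tau2,
        model=model, method="inverse_variance", excluded=excluded,
        review_id=review_id, n_participants=n_participants,
    )


def pool_mantel_haenszel(
    trials: Sequence[TrialRecord],
    correction: str = "constant_half",
    *,
    review_id: str | None = None,
) -> MetaResult:
    """Mantel-Haenszel fixed-effect pooling of 2x2 tables.

    OR_MH = sum(a_i d_i / N_i) / sum(b_i c_i / N_i); the standard error
    of ln(OR_MH) follows Robins, Breslow & Greenland.  Cochran's Q uses
    per-trial inverse-variance weights about ln(OR_MH).  Zero-cell
    tables receive the same continuity handling as :func:`trial_effect`
    throughout; no-information trials are excluded.
    """
    kept: list[tuple[float, float, float, float]] = []
    effects: list[EffectEstimate] = []
    excluded: list[str] = []
    n_participants = 0
    for trial in trials:
        cells = _cells(trial, correction)
        if cells is None:
            excluded.append(trial.trial_id)
            continue
        a, b, c, d, corrected = cells
        kept.append((a, b, c, d))
        effects.append(
            EffectEstimate(
                trial_id=trial.trial_id,
                log_or=math.log(a * d / (b * c)),
                se=math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
                corrected=corrected,
            )
        )
        n_participants += trial.n_total
    if not kept:
        raise EmptyAnalysisError(
            f"review {review_id!r}: every trial excluded (no-information tables)"
            if review_id
            else "every trial excluded (no-information tables)"
        )
    a = np.array([cell[0] for cell in kept])
    b = np.array([cell[1] for cell in kept])
    c = np.array([cell[2] for cell in kept])
    d = np.array([cell[3] for cell in kept])
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    sr, ss = float(np.sum(r)), float(np.sum(s))
    if sr == 0 or ss == 0:
        raise EmptyAnalysisError("Mantel-Haenszel sums degenerate (zero numerator or denominator)")
    log_or_mh = math.log(sr / ss)
    p = (a + d) / n
    q_ = (b + c) / n
    var = (
        float(np.sum(p * r)) / (2 * sr**2)
        + float(np.sum(p * s + q_ * r)) / (2 * sr * ss)
        + float(np.sum(q_ * s)) / (2 * ss**2)
    )
    se = math.sqrt(var)
    w = np.array([1.0 / e.se**2 for e in effects])
    theta = np.array([e.log_or for e in effects])
    q_het = float(np.sum(w * (theta - log_or_mh) ** 2))
    df = len(effects) - 1
    return _finish(
        effects=effects, pooled=log_or_mh, se=se, q=q_het, df=df, tau2=0.0,
        model="fixed", method="mantel_haenszel", excluded=excluded,
        review_id=review_id, n_participants=n_participants,
    )


def pool_trials(
    trials: Sequence[TrialRecord],
    config: OutcomeConfig,
    *,
    review_id: str | None = None,
) -> MetaResult:
    """Pool trials with the model/method/correction a review reported.

    Fixed-effect Mantel-Haenszel goes through
    :func:`pool_mantel_haenszel`; every other combination is pooled by
    inverse variance on per-trial log odds ratios (a random-effects
    request always uses inverse variance with DerSimonian-Laird tau^2,
    regardless of the stated method).
    """
    if not trials:
        raise EmptyAnalysisError("no trials to pool")
    if config.method == "mantel_haenszel" and config.model == "fixed":
        return pool_mantel_haenszel(
            trials, config.continuity_correction, review_id=review_id
        )
    effects, excluded = trial_effects(trials, config.continuity_correction)
    if not effects:
        raise EmptyAnalysisError(
            f"review {review_id!r}: every trial excluded (no-information tables)"
        )
    n_participants = sum(
        t.n_total for t in trials if t.trial_id not in set(excluded)
    )
    return pool_inverse_variance(
        effects,
        model=config.model,
        excluded=excluded,
        review_id=review_id,
        n_participants=n_participants,
    )


def subgroup_difference(groups: Sequence[MetaResult]) -> SubgroupComparison:
    """Chi-square test for differences between pooled subgroup effects.

    Q_between = sum_g w_g (theta_g - theta_bar)^2 with w_g = 1/se_g^2,
    referred to chi-square with (number of groups - 1) degrees of
    freedom.
    """
    if len(groups) < 2:
        raise ValidationError("subgroup difference needs at least two groups")
    theta = np.array([g.pooled_log_or for g in groups])
    w = np.array([1.0 / g.se**2 for g in groups])
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(w))):
        raise ValidationError("non-finite subgroup estimate")
    mu = float(np.sum(w * theta) / np.sum(w))
    q_between = float(np.sum(w * (theta - mu) ** 2))
    df = len(groups) - 1
    p = float(stats.chi2.sf(q_between, df))
    return SubgroupComparison(q_between=q_between, df=df, p_value=p)


def invert_direction(result: MetaResult) -> MetaResult:
    """Flip the effect direction so that OR < 1 favours the treatment.

    Negates the pooled log OR and reciprocates/swaps the ratio-scale
    bounds; the standard error and all heterogeneity statistics are
    unchanged.  Applying it twice is the identity.
    """
    return dataclasses.replace(
        result,
        pooled_log_or=-result.pooled_log_or,
        or_point=1.0 / result.or_point,
        ci_low=1.0 / result.ci_high,
        ci_high=1.0 / result.ci_low,
    )
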