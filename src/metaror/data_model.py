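"""Trial-level data model and delimited-text I/O.

A meta-epidemiological dataset is a flat table of randomized trials, one
row per trial, each belonging to a systematic review (``review_id``) and
carrying a 2x2 binary-outcome table (events / total per arm), the trial's
publication language, the target population, and six Cochrane risk-of-bias
(ROB) domain judgements.  A companion table of per-review outcome
configurations records how each review pooled its outcome (fixed or random
model, Mantel-Haenszel or inverse-variance method, zero-cell handling, and
whether the odds-ratio direction must be flipped so that OR < 1 favours
the experimental treatment).

All readers validate eagerly and raise :class:`ValidationError` naming the
offending row and column; a dataset is either fully valid or not loaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ROB_DOMAINS",
    "LANGUAGES",
    "POPULATIONS",
    "ROB_RATINGS",
    "OUTCOME_ROLES",
    "MODELS",
    "METHODS",
    "CORRECTIONS",
    "TRIAL_COLUMNS",
    "CONFIG_COLUMNS",
    "ValidationError",
    "TrialRecord",
    "OutcomeConfig",
    "ReviewDataset",
    "read_trials",
    "write_trials",
    "read_outcome_configs",
    "write_outcome_configs",
]

#: The six Cochrane ROB-1 domains, in fixed canonical order.
ROB_DOMAINS: tuple[str, ...] = (
    "random_sequence_generation",
    "allocation_concealment",
    "blinding_participants_personnel",
    "blinding_outcome_assessment",
    "incomplete_outcome_data",
    "selective_reporting",
)

LANGUAGES: tuple[str, ...] = ("chinese", "other")
POPULATIONS: tuple[str, ...] = ("chinese", "non_chinese")
ROB_RATINGS: tuple[str, ...] = ("low", "high", "unclear")
OUTCOME_ROLES: tuple[str, ...] = ("primary", "secondary")
MODELS: tuple[str, ...] = ("fixed", "random")
METHODS: tuple[str, ...] = ("mantel_haenszel", "inverse_variance")
CORRECTIONS: tuple[str, ...] = ("none", "constant_half")

TRIAL_COLUMNS: tuple[str, ...] = (
    "review_id",
    "trial_id",
    "language",
    "population",
    "events_treat",
    "n_treat",
    "events_ctrl",
    "n_ctrl",
) + ROB_DOMAINS

CONFIG_COLUMNS: tuple[str, ...] = (
    "review_id",
    "outcome_name",
    "outcome_role",
    "model",
    "method",
    "continuity_correction",
    "invert_direction",
)


class ValidationError(ValueError):
    """A structurally invalid record, table, or configuration."""


def _check_enum(value: str, allowed: Sequence[str], what: str, where: str) -> str:
    if value not in allowed:
        raise ValidationError(
            f"{where}: {what} must be one of {', '.join(allowed)}; got {value!r}"
        )
    return value


@dataclass(frozen=True)
class TrialRecord:
    """One randomized trial: a 2x2 outcome table plus annotations.

    ``events_treat``/``n_treat`` are the event count and sample size of the
    experimental (acupuncture) arm, ``events_ctrl``/``n_ctrl`` of the
    comparator arm.  ``rob`` maps every ROB domain to a judgement in
    {low, high, unclear}.
    """

    review_id: str
    trial_id: str
    language: str
    population: str
    events_treat: int
    n_treat: int
    events_ctrl: int
    n_ctrl: int
    rob: Mapping[str, str]

    def __post_init__(self) -> None:
        where = f"trial {self.trial_id!r} in review {self.review_id!r}"
        _check_enum(self.language, LANGUAGES, "language", where)
        _check_enum(self.population, POPULATIONS, "population", where)
        for name, events, total in (
            ("treat", self.events_treat, self.n_treat),
            ("ctrl", self.events_ctrl, self.n_ctrl),
        ):
            if not isinstance(events, int) or not isinstance(total, int):
                raise ValidationError(f"{where}: counts must be integers")
            if total <= 0:
                raise ValidationError(f"{where}: n_{name}={total} must be positive")
            if events < 0:
                raise ValidationError(f"{where}: events_{name}={events} is negative")
            if events > total:
                raise ValidationError(
                    f"{where}: events_{name}={events} exceeds n_{name}={total}"
                )
        if set(self.rob) != set(ROB_DOMAINS):
            missing = sorted(set(ROB_DOMAINS) - set(self.rob))
            extra = sorted(set(self.rob) - set(ROB_DOMAINS))
            raise ValidationError(
                f"{where}: rob must contain exactly the six domains"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )
        for domain in ROB_DOMAINS:
            _check_enum(self.rob[domain], ROB_RATINGS, f"rob[{domain}]", where)
        # normalise to a plain dict in canonical domain order
        object.__setattr__(self, "rob", {d: self.rob[d] for d in ROB_DOMAINS})

    @property
    def n_total(self) -> int:
        return self.n_treat + self.n_ctrl


@dataclass(frozen=True)
class OutcomeConfig:
    """How one review pooled one analysed binary outcome."""

    review_id: str
    outcome_name: str
    outcome_role: str
    model: str
    method: str
    continuity_correction: str
    invert_direction: bool

    def __post_init__(self) -> None:
        where = f"outcome {self.outcome_name!r} in review {self.review_id!r}"
        _check_enum(self.outcome_role, OUTCOME_ROLES, "outcome_role", where)
        _check_enum(self.model, MODELS, "model", where)
        _check_enum(self.method, METHODS, "method", where)
        _check_enum(
            self.continuity_correction, CORRECTIONS, "continuity_correction", where
        )
        if not isinstance(self.invert_direction, bool):
            raise ValidationError(f"{where}: invert_direction must be boolean")


@dataclass(frozen=True)
class ReviewDataset:
    """A validated collection of trials and their per-review outcome configs."""

    trials: tuple[TrialRecord, ...]
    configs: tuple[OutcomeConfig, ...]

    def __init__(
        self,
        trials: Iterable[TrialRecord],
        configs: Iterable[OutcomeConfig],
    ) -> None:
        object.__setattr__(self, "trials", tuple(trials))
        object.__setattr__(self, "configs", tuple(configs))
        seen: set[tuple[str, str]] = set()
        for t in self.trials:
            key = (t.review_id, t.trial_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate trial id {t.trial_id!r} in review {t.review_id!r}"
                )
            seen.add(key)
        config_reviews = {c.review_id for c in self.configs}
        for t in self.trials:
            if t.review_id not in config_reviews:
                raise ValidationError(
                    f"review {t.review_id!r} has trials but no outcome config"
                )
        seen_cfg: set[tuple[str, str]] = set()
        for c in self.configs:
            key = (c.review_id, c.outcome_name)
            if key in seen_cfg:
                raise ValidationError(
                    f"duplicate outcome {c.outcome_name!r} in review {c.review_id!r}"
                )
            seen_cfg.add(key)

    @property
    def review_ids(self) -> tuple[str, ...]:
        """Review ids in first-appearance order over trials, then configs."""
        out: list[str] = []
        for t in self.trials:
            if t.review_id not in out:
                out.append(t.review_id)
        for c in self.configs:
            if c.review_id not in out:
                out.append(c.review_id)
        return tuple(out)

    def trials_for(self, review_id: str) -> tuple[TrialRecord, ...]:
        return tuple(t for t in self.trials if t.review_id == review_id)

    def configs_for(self, review_id: str) -> tuple[OutcomeConfig, ...]:
        return tuple(c for c in self.configs if c.review_id == review_id)


def _parse_count(token: str, row: int, column: str, positive: bool = False) -> int:
    try:
        value = int(token)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}, column {column!r}: {token!r} is not an integer"
        ) from None
    if value < 0:
        raise ValidationError(f"row {row}, column {column!r}: {value} is negative")
    if positive and value == 0:
        raise ValidationError(f"row {row}, column {column!r}: must be positive")
    return value


def _parse_bool(token: str, row: int, column: str) -> bool:
    lowered = str(token).strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ValidationError(f"row {row}, column {column!r}: {token!r} is not a boolean")


def _load_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def read_trials(
    path: str | Path, configs_path: str | Path | None = None
) -> ReviewDataset:
    """Read a trials CSV (and optionally a configs CSV) into a dataset.

    When ``configs_path`` is omitted, a default outcome configuration is
    synthesised per review (random-effects inverse variance, 0.5 continuity
    correction, no direction inversion) so the dataset invariant that every
    review carries a config still holds.  Rows are reported 1-based
    (excluding the header) in error messages.
    """
    frame = _load_table(path, TRIAL_COLUMNS)
    trials: list[TrialRecord] = []
    for i, raw in enumerate(frame.to_dict("records"), start=1):
        try:
            trials.append(
                TrialRecord(
                    review_id=str(raw["review_id"]),
                    trial_id=str(raw["trial_id"]),
                    language=str(raw["language"]),
                    population=str(raw["population"]),
                    events_treat=_parse_count(raw["events_treat"], i, "events_treat"),
                    n_treat=_parse_count(raw["n_treat"], i, "n_treat", positive=True),
                    events_ctrl=_parse_count(raw["events_ctrl"], i, "events_ctrl"),
                    n_ctrl=_parse_count(raw["n_ctrl"], i, "n_ctrl", positive=True),
                    rob={d: str(raw[d]) for d in ROB_DOMAINS},
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    if configs_path is not None:
        configs = read_outcome_configs(configs_path)
    else:
        configs = tuple(
            OutcomeConfig(
                review_id=rid,
                outcome_name="unnamed_outcome",
                outcome_role="primary",
                model="random",
                method="inverse_variance",
                continuity_correction="constant_half",
                invert_direction=False,
            )
            for rid in dict.fromkeys(t.review_id for t in trials)
        )
    return ReviewDataset(trials, configs)


def write_trials(dataset: ReviewDataset, path: str | Path) -> Path:
    """Write the trials of a dataset as CSV; inverse of :func:`read_trials`."""
    path = Path(path)
    rows = []
    for t in dataset.trials:
        row = {
            "review_id": t.review_id,
            "trial_id": t.trial_id,
            "language": t.language,
            "population": t.population,
            "events_treat": t.events_treat,
            "n_treat": t.n_treat,
            "events_ctrl": t.events_ctrl,
            "n_ctrl": t.n_ctrl,
        }
        row.update({d: t.rob[d] for d in ROB_DOMAINS})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def read_outcome_configs(path: str | Path) -> tuple[OutcomeConfig, ...]:
    frame = _load_table(path, CONFIG_COLUMNS)
    configs: list[OutcomeConfig] = []
    for i, raw in enumerate(frame.to_dict("records"), start=1):
        try:
            configs.append(
                OutcomeConfig(
                    review_id=str(raw["review_id"]),
                    outcome_name=str(raw["outcome_name"]),
                    outcome_role=str(raw["outcome_role"]),
                    model=str(raw["model"]),
                    method=str(raw["method"]),
                    continuity_correction=str(raw["continuity_correction"]),
                    invert_direction=_parse_bool(
                        raw["invert_direction"], i, "invert_direction"
                    ),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return tuple(configs)


def write_outcome_configs(
    configs: Iterable[OutcomeConfig], path: str | Path
) -> Path:
    path = Path(path)
    rows = [
        {
            "review_id": c.review_id,
            "outcome_name": c.outcome_name,
            "outcome_role": c.outcome_role,
            "model": c.model,
            "method": c.method,
            "continuity_correction": c.continuity_correction,
            "invert_direction": "true" if c.invert_direction else "false",
        }
        for c in configs
    ]
    frame = pd.DataFrame(rows, columns=list(CONFIG_COLUMNS))
    frame.to_csv(path, index=False)
    return path
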