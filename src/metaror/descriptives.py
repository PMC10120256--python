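"""Contribution accounting and risk-of-bias profiling.

Builds the three-level contribution table (reviews, trials, participants,
cross-classified by whether the review searched Chinese-language
bibliographic databases and by trial publication language), computes the
integer percentages used throughout such tables, the "X times higher"
fold-increase arithmetic, and per-domain risk-of-bias profiles split by
language.

All rounding is half-up: percentages are reported as integers and fold
increases to one decimal, computed on the already-rounded percentages
(the convention under which 54% vs 15% is a 2.6-fold increase).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import LANGUAGES, ROB_DOMAINS, TrialRecord, ValidationError

__all__ = [
    "LEVELS",
    "ReviewMeta",
    "ContributionTable",
    "build_contribution_table",
    "percent",
    "fold_increase",
    "rob_profile",
    "round_half_up",
]

#: Aggregation levels of the contribution table.
LEVELS: tuple[str, ...] = ("review", "trial", "participant")

#: Category labels per level; the first category is the "Chinese" one.
_CATEGORIES: dict[str, tuple[str, str]] = {
    "review": ("included_chinese", "no_chinese"),
    "trial": ("chinese", "other"),
    "participant": ("chinese", "other"),
}


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up."""
    if denominator <= 0:
        raise ValidationError(f"percent denominator must be positive; got {denominator}")
    if numerator < 0:
        raise ValidationError(f"percent numerator must be non-negative; got {numerator}")
    return int(round_half_up(100.0 * numerator / denominator))


def fold_increase(percent_a: int, percent_b: int) -> float:
    """Relative increase "(a - b) / b", one decimal, on rounded percentages.

    This is the "X times higher" convention: 54% vs 15% is a 2.6 times
    higher contribution.
    """
    if percent_b <= 0:
        raise ValidationError(f"fold_increase baseline must be positive; got {percent_b}")
    return round_half_up((percent_a - percent_b) / percent_b, 1)


@dataclass(frozen=True)
class ReviewMeta:
    """Review-level annotation: did the review search Chinese databases?"""

    review_id: str
    searched_chinese_databases: bool


@dataclass(frozen=True)
class ContributionTable:
    """Counts cross-classified by level, searched-flag, and category.

    ``cells`` maps ``(level, searched, category)`` to a non-negative
    count; totals are derived sums, so marginal consistency holds by
    construction.
    """

    cells: Mapping[tuple[str, bool, str], int]

    def __post_init__(self) -> None:
        for key, value in self.cells.items():
            level, searched, category = key
            if level not in LEVELS or category not in _CATEGORIES[level]:
                raise ValidationError(f"unknown contribution cell {key}")
            if not isinstance(value, int) or value < 0:
                raise ValidationError(f"cell {key} must be a non-negative integer")
        object.__setattr__(self, "cells", dict(self.cells))

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, bool, str], int]
    ) -> "ContributionTable":
        """Build directly from published cell counts (missing cells are 0)."""
        return cls(cells=dict(counts))

    def cell(self, level: str, searched: bool, category: str) -> int:
        return self.cells.get((level, searched, category), 0)

    def column_total(self, level: str, searched: bool) -> int:
        return sum(
            self.cell(level, searched, category) for category in _CATEGORIES[level]
        )

    def total(self, level: str) -> int:
        return self.column_total(level, True) + self.column_total(level, False)

    def percent_cell(self, level: str, searched: bool, category: str) -> int:
        """Integer percentage of a cell within its searched/not-searched column."""
        return percent(
            self.cell(level, searched, category), self.column_total(level, searched)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for category in _CATEGORIES[level]:
                searched_n = self.cell(level, True, category)
                not_searched_n = self.cell(level, False, category)
                rows.append(
                    {
                        "level": level,
                        "category": category,
                        "searched": searched_n,
                        "not_searched": not_searched_n,
                        "total": searched_n + not_searched_n,
                    }
                )
            rows.append(
                {
                    "level": level,
                    "category": "total",
                    "searched": self.column_total(level, True),
                    "not_searched": self.column_total(level, False),
                    "total": self.total(level),
                }
            )
        return pd.DataFrame(rows)


def build_contribution_table(
    reviews: Sequence[ReviewMeta], trials: Iterable[TrialRecord]
) -> ContributionTable:
    """Count reviews, trials, and participants by search flag and language.

    Every trial's review must appear in ``reviews`` (the searched flag is
    review-level metadata that the trial table does not carry).
    """
    flag_by_review = {r.review_id: r.searched_chinese_databases for r in reviews}
    cells: dict[tuple[str, bool, str], int] = {}
    for level in LEVELS:
        for searched in (True, False):
            for category in _CATEGORIES[level]:
                cells[(level, searched, category)] = 0

    reviews_with_chinese: set[str] = set()
    for trial in trials:
        searched = flag_by_review.get(trial.review_id)
        if searched is None:
            raise ValidationError(
                f"review {trial.review_id!r} lacks a searched_chinese_databases flag"
            )
        cells[("trial", searched, trial.language)] += 1
        cells[("participant", searched, trial.language)] += trial.n_total
        if trial.language == "chinese":
            reviews_with_chinese.add(trial.review_id)

    for review in reviews:
        category = (
            "included_chinese"
            if review.review_id in reviews_with_chinese
            else "no_chinese"
        )
        cells[("review", review.searched_chinese_databases, category)] += 1

    return ContributionTable(cells=cells)


def rob_profile(
    trials: Sequence[TrialRecord], split_by: str = "language"
) -> dict[str, dict[str, int]]:
    """Percent of trials rated high or unclear, per ROB domain and language.

    Returns ``{domain: {language: integer percent}}``; a language with no
    trials is absent from the inner mapping rather than reported as 0.
    """
    if split_by != "language":
        raise ValidationError(f"unsupported split_by {split_by!r}")
    if not trials:
        raise ValidationError("rob_profile needs at least one trial")
    profile: dict[str, dict[str, int]] = {}
    for domain in ROB_DOMAINS:
        profile[domain] = {}
        for language in LANGUAGES:
            subset = [t for t in trials if t.language == language]
            if not subset:
                continue
            high_unclear = sum(1 for t in subset if t.rob[domain] in ("high", "unclear"))
            profile[domain][language] = percent(high_unclear, len(subset))
    return profile
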