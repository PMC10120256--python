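"""Deterministic choice of one analysed binary outcome per review.

Reviews often report several binary outcomes; the two-stage design needs
exactly one per review so that each review contributes one ratio of odds
ratios.  The hierarchical rule is:

1. consider primary outcomes whose forest plot includes trials in both
   publication languages;
2. among those, take the one with the largest number of trials;
3. break ties by the largest total sample size;
4. if no primary outcome qualifies, apply the same rule to secondary
   outcomes; if none qualifies, the review is excluded from the
   quantitative analysis.

Residual ties are broken lexicographically by outcome name so the choice
is deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import (
    LANGUAGES,
    OUTCOME_ROLES,
    OutcomeConfig,
    ReviewDataset,
    ValidationError,
)

__all__ = ["OutcomeCandidate", "select_outcome", "candidates_from_dataset", "select_config"]


@dataclass(frozen=True)
class OutcomeCandidate:
    """One binary outcome of one review, as seen by the selection rule."""

    review_id: str
    outcome_name: str
    outcome_role: str
    has_both_languages: bool
    k_trials: int
    total_sample: int

    def __post_init__(self) -> None:
        if self.outcome_role not in OUTCOME_ROLES:
            raise ValidationError(
                f"outcome {self.outcome_name!r}: unknown role {self.outcome_role!r}"
            )
        if self.k_trials < 1:
            raise ValidationError(f"outcome {self.outcome_name!r}: k_trials must be >= 1")
        if self.total_sample < self.k_trials:
            raise ValidationError(
                f"outcome {self.outcome_name!r}: total_sample < k_trials"
            )


def select_outcome(candidates: list[OutcomeCandidate]) -> OutcomeCandidate | None:
    """Apply the hierarchical selection rule; None means review excluded."""
    if not candidates:
        return None
    review_ids = {c.review_id for c in candidates}
    if len(review_ids) > 1:
        raise ValidationError(
            f"candidates span several reviews: {sorted(review_ids)}"
        )
    for role in ("primary", "secondary"):
        eligible = [
            c for c in candidates if c.outcome_role == role and c.has_both_languages
        ]
        if eligible:
            return sorted(
                eligible,
                key=lambda c: (-c.k_trials, -c.total_sample, c.outcome_name),
            )[0]
    return None


def candidates_from_dataset(
    dataset: ReviewDataset, review_id: str
) -> list[OutcomeCandidate]:
    """Build candidates for a review from its trials and outcome configs.

    ``has_both_languages`` is recomputed from the trial records rather
    than trusted from any input annotation.
    """
    trials = dataset.trials_for(review_id)
    if not trials:
        return []
    languages = {t.language for t in trials}
    both = set(LANGUAGES) <= languages
    k = len(trials)
    n = sum(t.n_total for t in trials)
    return [
        OutcomeCandidate(
            review_id=review_id,
            outcome_name=c.outcome_name,
            outcome_role=c.outcome_role,
            has_both_languages=both,
            k_trials=k,
            total_sample=n,
        )
        for c in dataset.configs_for(review_id)
    ]


def select_config(dataset: ReviewDataset, review_id: str) -> OutcomeConfig | None:
    """The outcome configuration chosen by the selection rule, if any."""
    chosen = select_outcome(candidates_from_dataset(dataset, review_id))
    if chosen is None:
        return None
    for config in dataset.configs_for(review_id):
        if config.outcome_name == chosen.outcome_name:
            return config
    return None
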