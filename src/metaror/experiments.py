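"""Monte-Carlo evaluation of the two-stage pipeline on synthetic collections.

These helpers run the full pipeline (generate -> stratify -> pool ->
ROR -> pool RORs) repeatedly under a fixed generative configuration,
varying only the seed, and summarise operating characteristics: the
distribution of the pooled ROR point estimate, confidence-interval
coverage of the true ROR, and the CI-excludes-1 rejection rate used for
type-I-error checks under a null configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from .ror import PooledROR, run_analysis_preset
from .simulate import SimulationConfig, generate

__all__ = ["ReplicateSummary", "run_replicates", "pooled_ror_once"]

_SEED_MODULUS = 2**31 - 1


@dataclass(frozen=True)
class ReplicateSummary:
    """Operating characteristics over repeated synthetic collections."""

    n_replicates: int
    points: tuple[float, ...]
    coverage_rate: float | None
    rejection_rate: float

    @property
    def mean_point(self) -> float:
        return math.exp(
            sum(math.log(p) for p in self.points) / len(self.points)
        )


def pooled_ror_once(
    config: SimulationConfig, preset: str = "language_overall", row: int = 0
) -> PooledROR | None:
    """One pipeline run; the pooled ROR of the requested report row."""
    dataset, _ = generate(config)
    report = run_analysis_preset(dataset, preset)
    return report.rows[row].pooled


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    *,
    preset: str = "language_overall",
    row: int = 0,
    true_ror: float | None = None,
    seed_start: int = 0,
) -> ReplicateSummary:
    """Repeat the full pipeline, re-seeding the generator per replicate.

    Replicate ``i`` runs with seed ``(seed_start + i) mod (2^31 - 1)``.
    ``coverage_rate`` is the share of replicates whose 95% CI contains
    ``true_ror`` (None when no truth is supplied); ``rejection_rate`` is
    the share whose CI excludes 1.
    """
    points: list[float] = []
    covered = 0
    rejected = 0
    produced = 0
    for i in range(n_replicates):
        replicate_config = dataclasses.replace(
            config, seed=(seed_start + i) % _SEED_MODULUS
        )
        pooled = pooled_ror_once(replicate_config, preset=preset, row=row)
        if pooled is None:
            continue
        produced += 1
        points.append(pooled.ror)
        if true_ror is not None and pooled.ci_low <= true_ror <= pooled.ci_high:
            covered += 1
        if pooled.ci_high < 1.0 or pooled.ci_low > 1.0:
            rejected += 1
    if produced == 0:
        raise ValueError("no replicate produced a pooled ROR")
    return ReplicateSummary(
        n_replicates=produced,
        points=tuple(points),
        coverage_rate=(covered / produced) if true_ror is not None else None,
        rejection_rate=rejected / produced,
    )
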