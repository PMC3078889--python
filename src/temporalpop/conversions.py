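"""Unit conversions for reporting demographic quantities.

Gorilla generation time is taken as 20 years, so times inferred in
generations are reported in years by a factor of 20.
"""

from __future__ import annotations

__all__ = [
    "GENERATION_TIME_YEARS",
    "years_from_generations",
    "generations_from_years",
    "per_generation_decline",
]

GENERATION_TIME_YEARS = 20.0


def years_from_generations(generations: float, generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in generations to years."""
    return generations * generation_time


def generations_from_years(years: float, generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in years to generations."""
    return years / generation_time


def per_generation_decline(fold_reduction: float, n_generations: float) -> float:
    """Constant per-generation loss rate implied by an overall fold reduction.

    A population shrinking to 1/``fold_reduction`` of its size over
    ``n_generations`` generations at a constant rate loses a fraction
    ``1 - fold_reduction**(-1/n_generations)`` of its size each generation
    (e.g. a 60-fold decrease over 16 generations is a ~23% loss per
    generation).
    """
    if fold_reduction <= 0 or n_generations <= 0:
        raise ValueError("fold_reduction and n_generations must be positive")
    return 1.0 - fold_reduction ** (-1.0 / n_generations)
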