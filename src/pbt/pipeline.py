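"""End-to-end orchestration: clean both arms, profile, and evaluate.

These helpers wire the modules together the way the command line does:
meal-agnostic peak exclusion on one arm, the announced-meal comparator on
the other, hourly profiles from the cleaned data, then the noninferiority,
precision and interval-classification statistics.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .io_formats import DailySeries, MealEvent
from .peaks import (
    DEFAULT_NOISE_FLOOR,
    DEFAULT_PERCENTILE,
    DEFAULT_REL_HEIGHT,
    clean_days,
    clean_days_with_meals,
)
from .profile import build_profile, hourly_changes, hourly_median_deltas
from .stats import (
    DEFAULT_CONF,
    DEFAULT_MARGIN,
    classify_intervals,
    cohort_summary,
    noninferiority_test,
    precision_vs_meals,
)

log = logging.getLogger(__name__)


def absolute_deviations(cleaned) -> list[float]:
    """Per-(date, hour) absolute relative-change deviations from 0 mg/dL."""
    return [abs(c.delta) for c in hourly_changes(cleaned)]


def evaluate_participant(
    days: list[DailySeries],
    meals: list[MealEvent],
    participant: str = "participant",
    margin: float = DEFAULT_MARGIN,
    conf: float = DEFAULT_CONF,
    optimal_tol: float = 0.0,
    percentile: float = DEFAULT_PERCENTILE,
    rel_height: float = DEFAULT_REL_HEIGHT,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    welch: bool = False,
) -> dict:
    """Run both exclusion arms for one participant and all three evaluations.

    Returns a dict with ``profile`` (24 graded hourly distributions from the
    meal-agnostic arm), ``noninferiority``, ``precision`` and
    ``classification`` entries.
    """
    cleaned_nomeal, flagged, _ = clean_days(
        days, percentile=percentile, rel_height=rel_height, noise_floor=noise_floor
    )
    cleaned_meal, _ = clean_days_with_meals(days, meals)

    profile = build_profile(cleaned_nomeal)
    nit = noninferiority_test(
        absolute_deviations(cleaned_nomeal),
        absolute_deviations(cleaned_meal),
        margin=margin,
        welch=welch,
    )
    prec = precision_vs_meals(flagged, meals, conf=conf)
    classification = classify_intervals(
        {participant: hourly_median_deltas(profile)}, optimal_tol=optimal_tol
    )
    return {
        "participant": participant,
        "profile": profile,
        "noninferiority": nit,
        "precision": prec,
        "classification": classification,
    }


def evaluate_cohort(
    participants: Mapping[str, tuple[list[DailySeries], list[MealEvent]]],
    **kwargs,
) -> dict:
    """Per-participant evaluations plus the pooled cohort summary."""
    per = {
        pid: evaluate_participant(days, meals, participant=pid, **kwargs)
        for pid, (days, meals) in participants.items()
    }
    classifications = [c for r in per.values() for c in r["classification"]]
    return {
        "participants": per,
        "cohort": cohort_summary(classifications, conf=kwargs.get("conf", DEFAULT_CONF)),
    }
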