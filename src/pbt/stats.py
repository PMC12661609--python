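"""Evaluation statistics for basal-rate adequacy.

Three evaluations are implemented:

* a one-sided noninferiority test with a relative margin (default 20%) on
  mean absolute hourly deviation, comparing the meal-agnostic exclusion arm
  against the meal-announcement comparator arm;
* precision of meal-peak flagging against annotated meals, with Wilson score
  confidence intervals;
* the interindividual classification of each participant-hour as excessive
  (< 0 mg/dL median hourly change), insufficient (> 0) or optimal (= 0)
  insulin, with cohort summaries.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .io_formats import MealEvent, ValidationError
from .peaks import Peak
from .profile import HourlyDistribution

log = logging.getLogger(__name__)

DEFAULT_MARGIN = 0.20
DEFAULT_CONF = 0.95
#: Fraction of peak-bearing days without meal annotations above which the
#: participant's precision estimate is flagged low quality.
LOW_QUALITY_MISSING_FRACTION = 0.25


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------


def wilson_interval(k: int, n: int, conf: float = DEFAULT_CONF) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n.

    Returns (lo, hi) as fractions.  The Wilson interval has markedly better
    small-sample coverage than the Wald normal approximation and never
    escapes [0, 1]; with k = 0 the lower bound is exactly 0.
    """
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# noninferiority
# ---------------------------------------------------------------------------


@dataclass
class NoninferiorityResult:
    """One-sided margin test of the meal-agnostic arm against the comparator.

    H0: mean(|dev| no-meal) >= (1 + margin) * mean(|dev| meal)
    H1: mean(|dev| no-meal) <  (1 + margin) * mean(|dev| meal)

    Negative ``t_stat`` favors noninferiority; ``p_one_sided`` < 0.05
    concludes it.  ``p_two_sided`` is reported alongside for reference.
    """

    t_stat: float
    df: float
    p_one_sided: float
    p_two_sided: float
    margin: float
    mean_nomeal: float
    mean_meal: float
    n_nomeal: int
    n_meal: int


def noninferiority_test(
    dev_nomeal: Sequence[float],
    dev_meal: Sequence[float],
    margin: float = DEFAULT_MARGIN,
    welch: bool = False,
) -> NoninferiorityResult:
    """Scaled two-sample t-test of absolute deviations against a relative margin.

    The comparator sample is inflated by (1 + margin) and a two-sample
    t-test run on the shifted null; with ``welch=False`` (default) the
    pooled-variance form with df = n1 + n2 - 2 is used, otherwise the
    Welch–Satterthwaite form.

    Inputs are the per-(date, hour) absolute relative-change deviations of
    each exclusion arm; both must have length >= 2.
    """
    x = np.asarray(dev_nomeal, dtype=float)
    y_raw = np.asarray(dev_meal, dtype=float)
    if len(x) < 2 or len(y_raw) < 2:
        raise ValueError("each deviation sample must have length >= 2")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    y = (1.0 + margin) * y_raw
    n1, n2 = len(x), len(y)
    mx, my = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        ) if se > 0 else float(n1 + n2 - 2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    diff = mx - my
    if se == 0:
        if diff == 0:
            raise ValidationError(
                "degenerate noninferiority input: zero variance and equal means"
            )
        t = math.inf if diff > 0 else -math.inf
    else:
        t = diff / se
    p_one = float(sps.t.cdf(t, df))
    p_two = float(2 * min(sps.t.cdf(t, df), sps.t.sf(t, df)))
    return NoninferiorityResult(
        t_stat=float(t),
        df=float(df) if welch else int(df),
        p_one_sided=p_one,
        p_two_sided=p_two,
        margin=margin,
        mean_nomeal=float(mx),
        mean_meal=float(y_raw.mean()),
        n_nomeal=n1,
        n_meal=n2,
    )


# ---------------------------------------------------------------------------
# precision against meal annotations
# ---------------------------------------------------------------------------


@dataclass
class PrecisionResult:
    """Fraction of flagged peaks matched to an annotated meal, with Wilson CI.

    Peaks on dates with no meal annotations at all are removed from the
    denominator (no reference exists) and reported via
    ``missing_meal_days``; ``low_quality`` is set when the missing fraction
    exceeds the configured threshold.
    """

    n_flagged: int
    n_matched: int
    precision: float | None
    ci_lo: float | None
    ci_hi: float | None
    low_quality: bool
    missing_meal_days: int


def precision_vs_meals(
    flagged: Sequence[Peak],
    meals: Sequence[MealEvent],
    days_with_meal_file: set[dt.date] | None = None,
    conf: float = DEFAULT_CONF,
    low_quality_threshold: float = LOW_QUALITY_MISSING_FRACTION,
) -> PrecisionResult:
    """Match flagged peaks to meals in a width-adaptive window.

    A peak matches when some meal timestamp lies in
    ``[t_apex - width/2 - 1h, t_apex + 1h]`` — one hour before the
    estimated excursion start (apex minus half the width) to one hour after
    the apex.  ``days_with_meal_file`` defaults to the set of dates carrying
    at least one meal annotation.
    """
    if days_with_meal_file is None:
        days_with_meal_file = {m.ts.date() for m in meals}
    meal_times = sorted(m.ts for m in meals)

    peak_dates = {p.date for p in flagged}
    missing_dates = {d for d in peak_dates if d not in days_with_meal_file}
    considered = [p for p in flagged if p.date in days_with_meal_file]

    n_matched = 0
    for p in considered:
        lo = p.t_apex - dt.timedelta(hours=p.width / 2.0 + 1.0)
        hi = p.t_apex + dt.timedelta(hours=1.0)
        if any(lo <= t <= hi for t in meal_times):
            n_matched += 1

    n_flagged = len(considered)
    if n_flagged == 0:
        log.warning("no flagged peaks on meal-annotated dates; precision undefined")
        precision = ci_lo = ci_hi = None
    else:
        precision = n_matched / n_flagged
        ci_lo, ci_hi = wilson_interval(n_matched, n_flagged, conf)
    low_quality = bool(
        peak_dates and len(missing_dates) / len(peak_dates) > low_quality_threshold
    )
    return PrecisionResult(
        n_flagged=n_flagged,
        n_matched=n_matched,
        precision=precision,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        low_quality=low_quality,
        missing_meal_days=len(missing_dates),
    )


# ---------------------------------------------------------------------------
# interindividual classification
# ---------------------------------------------------------------------------


@dataclass
class IntervalClassification:
    """One participant-hour of the composite day, classified by median delta."""

    participant: str
    hour: int
    category: str  # excessive | insufficient | optimal
    median_delta: float


def _categorize(median: float, tol: float) -> str:
    if median < -tol:
        return "excessive"
    if median > tol:
        return "insufficient"
    return "optimal"


def classify_intervals(
    per_participant: Mapping[str, Sequence[HourlyDistribution] | Mapping[int, float | None]],
    optimal_tol: float = 0.0,
) -> list[IntervalClassification]:
    """Classify every defined participant-hour by the sign of its median delta.

    A negative median hourly change marks excessive insulin (glucose driven
    down over fasting hours), positive marks insufficient, and exactly zero
    (within ``optimal_tol``, default 0) marks an optimal basal setting.
    Hours with an undefined median are omitted with a log note.
    """
    out: list[IntervalClassification] = []
    for pid, dists in per_participant.items():
        if isinstance(dists, Mapping):
            medians: Iterable[tuple[int, float | None]] = sorted(dists.items())
        else:
            medians = [(d.hour, d.median) for d in dists]
        for hour, med in medians:
            if med is None:
                log.info("participant %s hour %d has no data; omitted", pid, hour)
                continue
            out.append(IntervalClassification(pid, hour, _categorize(med, optimal_tol), float(med)))
    return out


@dataclass
class CohortSummary:
    """Cohort-level view of the interval classifications.

    ``pct_nonoptimal`` and its Wilson CI are percentages.  The daily
    cumulative value per participant is the sum over their composite hours
    of the absolute median delta — the total unsigned glucose drift a day of
    the current basal program accumulates; its mean, population SD and
    maximum over participants are reported.  Variances (sample, ddof=1) of
    the pooled excessive and insufficient median sets allow comparing
    consistency of the two failure directions.
    """

    n_intervals: int
    n_nonoptimal: int
    pct_nonoptimal: float
    pct_ci_lo: float
    pct_ci_hi: float
    optimal_hours_per_day: float
    delta_min: float
    delta_max: float
    daily_cumulative_mean: float
    daily_cumulative_sd: float
    daily_cumulative_peak: float
    variance_excessive: float | None
    variance_insufficient: float | None
    n_participants: int


def cohort_summary(
    classifications: Sequence[IntervalClassification], conf: float = DEFAULT_CONF
) -> CohortSummary:
    """Aggregate interval classifications across the cohort."""
    if not classifications:
        raise ValueError("cohort_summary requires at least one classified interval")
    participants = sorted({c.participant for c in classifications})
    n_participants = len(participants)
    n_intervals = len(classifications)
    n_optimal = sum(1 for c in classifications if c.category == "optimal")
    n_nonoptimal = n_intervals - n_optimal
    ci_lo, ci_hi = wilson_interval(n_nonoptimal, n_intervals, conf)

    medians = np.array([c.median_delta for c in classifications])
    cumulative = {
        pid: sum(abs(c.median_delta) for c in classifications if c.participant == pid)
        for pid in participants
    }
    cum = np.array([cumulative[p] for p in participants])
    excessive = np.array([c.median_delta for c in classifications if c.category == "excessive"])
    insufficient = np.array(
        [c.median_delta for c in classifications if c.category == "insufficient"]
    )
    return CohortSummary(
        n_intervals=n_intervals,
        n_nonoptimal=n_nonoptimal,
        pct_nonoptimal=100.0 * n_nonoptimal / n_intervals,
        pct_ci_lo=100.0 * ci_lo,
        pct_ci_hi=100.0 * ci_hi,
        optimal_hours_per_day=n_optimal / n_participants,
        delta_min=float(medians.min()),
        delta_max=float(medians.max()),
        daily_cumulative_mean=float(cum.mean()),
        daily_cumulative_sd=float(cum.std(ddof=0)),
        daily_cumulative_peak=float(cum.max()),
        variance_excessive=float(excessive.var(ddof=1)) if len(excessive) >= 2 else None,
        variance_insufficient=float(insufficient.var(ddof=1)) if len(insufficient) >= 2 else None,
        n_participants=n_participants,
    )
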