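"""Composite 24-hour profile of hourly relative glucose changes.

After meal-influenced segments are excised, every remaining day is overlaid
onto a single 00:00–23:59 grid with 1-minute slots (the composite day).  For
each (date, hour) with at least two retained samples, the hourly relative
change is the last sample's glucose minus the first's: 0 mg/dL means the
basal rate held glucose flat over that fasting hour, a positive delta points
to insufficient basal insulin, a negative one to excess.

Per-hour box-plot statistics are pooled over days, and each hour receives a
low/medium/high reliability grade from its sample count relative to the 50th
and 70th percentiles of all 24 hourly counts.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import CleanedDay

log = logging.getLogger(__name__)

#: Figure annotation band (mg/dL) sometimes drawn around hourly box plots;
#: purely visual, no computational role.
VISUAL_BAND_MGDL = 36.0


@dataclass
class HourlyRelChange:
    """Relative glucose change over one clock hour of one day."""

    date: dt.date
    hour: int  # 0–23, half-open hour [h:00, h+1:00)
    delta: float  # mg/dL, last sample minus first sample in the hour
    n_points: int  # retained samples in the hour; defined only when >= 2


@dataclass
class HourlyDistribution:
    """Box-plot summary of one composite hour's pooled day-deltas."""

    hour: int
    median: float | None
    q1: float | None
    q3: float | None
    whisker_lo: float | None
    whisker_hi: float | None
    outliers: list[float] = field(default_factory=list)
    n: int = 0
    reliability: str = "low"  # low | medium | high


def pivot(cleaned: list[CleanedDay]) -> pd.DataFrame:
    """Overlay cleaned days onto a days × 1440 minute-of-day grid.

    Rows are dates, columns minute-of-day 0–1439; a cell holds the glucose
    of the unique sample whose timestamp truncates to that minute, NaN where
    no sample remains.  Total non-NaN cells equals total cleaned samples.
    """
    if not cleaned:
        raise ValueError("pivot requires at least one cleaned day")
    dates = [d.date for d in cleaned]
    grid = pd.DataFrame(np.nan, index=pd.Index(dates, name="date"), columns=range(1440))
    for row, day in enumerate(cleaned):
        for s in day.samples:
            minute = s.ts.hour * 60 + s.ts.minute
            if not np.isnan(grid.iat[row, minute]):
                raise ValueError(
                    f"two samples truncate to minute {minute} on {day.date}"
                )
            grid.iat[row, minute] = s.value
    return grid


def hourly_changes(cleaned: list[CleanedDay]) -> list[HourlyRelChange]:
    """Per-(date, hour) last-minus-first deltas; hours with < 2 samples are omitted."""
    out: list[HourlyRelChange] = []
    for day in cleaned:
        by_hour: dict[int, list[float]] = {}
        for s in day.samples:  # samples are time-ordered
            by_hour.setdefault(s.ts.hour, []).append(s.value)
        for hour in sorted(by_hour):
            vals = by_hour[hour]
            if len(vals) >= 2:
                out.append(HourlyRelChange(day.date, hour, vals[-1] - vals[0], len(vals)))
    return out


def summarize_hour(changes: list[HourlyRelChange], hour: int) -> HourlyDistribution:
    """Box-plot statistics of one hour's deltas pooled over all days.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme points within 1.5·IQR of the quartiles; points
    beyond are listed as outliers.  An hour with no contributing deltas gets
    null statistics and low reliability.
    """
    deltas = np.array([c.delta for c in changes if c.hour == hour], dtype=float)
    n = len(deltas)
    if n == 0:
        return HourlyDistribution(hour, None, None, None, None, None, [], 0, "low")
    q1, med, q3 = np.percentile(deltas, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = deltas[(deltas >= lo_fence) & (deltas <= hi_fence)]
    outliers = sorted(float(d) for d in deltas[(deltas < lo_fence) | (deltas > hi_fence)])
    return HourlyDistribution(
        hour,
        float(med),
        float(q1),
        float(q3),
        float(inside.min()),
        float(inside.max()),
        outliers,
        n,
    )


def grade_reliability(distributions: list[HourlyDistribution]) -> list[HourlyDistribution]:
    """Assign low/medium/high from each hour's n against the 24-hour count distribution.

    With P50/P70 the 50th and 70th percentiles of the 24 n-values:
    low if n < P50, medium if P50 <= n < P70, high if n >= P70.
    """
    if len(distributions) != 24:
        raise ValueError(f"expected 24 hourly distributions, got {len(distributions)}")
    ns = np.array([d.n for d in distributions], dtype=float)
    p50, p70 = np.percentile(ns, [50, 70])
    for d in distributions:
        d.reliability = "low" if d.n < p50 else ("medium" if d.n < p70 else "high")
    return distributions


def build_profile(cleaned: list[CleanedDay]) -> list[HourlyDistribution]:
    """Hourly changes -> 24 graded box-plot summaries (the hourly profile)."""
    changes = hourly_changes(cleaned)
    dists = [summarize_hour(changes, h) for h in range(24)]
    return grade_reliability(dists)


def hourly_median_deltas(profile: list[HourlyDistribution]) -> dict[int, float | None]:
    """Hour -> median delta (None where the hour had no data)."""
    return {d.hour: d.median for d in profile}
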