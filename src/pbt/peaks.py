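"""Meal-peak detection and excision from daily CGM traces.

The cleaning algorithm runs day by day: low-pass filter the trace, find every
strict local maximum, measure each peak's geometric height (apex minus the
*deeper* of the two neighboring minima) and its width by linear interpolation
at a fractional height, flag peaks whose height or width reaches the day's
95th percentile as meal-likely, and cut a window from 1 hour before to
3 hours after each flagged apex.  Windows that run past midnight carry the
overflow into the next calendar date; windows that would start before the
day's 00:00 are clamped to it.

Note the height convention: the base is the deeper (lower) neighboring
minimum, the opposite choice from the usual topographic-prominence base.
``detect_peaks(..., height_base="higher")`` switches to the prominence-style
base for comparison.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import DailySeries, GlucoseSample, MealEvent

log = logging.getLogger(__name__)

#: Minimum geometric height (mg/dL) for a local maximum to count as a peak.
#: Integer-quantized CGM otherwise produces spurious 1–2 mg/dL "peaks".
DEFAULT_NOISE_FLOOR = 5.0
#: Fraction of the height at which the width is interpolated.
DEFAULT_REL_HEIGHT = 0.5
#: Outlier percentile for the meal-likely flag.
DEFAULT_PERCENTILE = 95.0
#: Exclusion window around a flagged apex, minutes before/after.
DEFAULT_PRE_MINUTES = 60.0
DEFAULT_POST_MINUTES = 180.0
#: Post-meal exclusion horizon for the meal-annotation comparator arm.
MEAL_WINDOW_MINUTES = 240.0


@dataclass
class Peak:
    """A detected glucose peak with its geometric measurements."""

    t_apex: dt.datetime
    apex_value: float
    height: float  # mg/dL, apex minus deeper neighboring minimum
    width: float  # hours, at rel_height of the height
    t_left_base: dt.datetime
    t_right_base: dt.datetime
    edge_truncated: bool = False  # width hit the series edge on one side

    @property
    def date(self) -> dt.date:
        return self.t_apex.date()


@dataclass(frozen=True)
class ExclusionWindow:
    """Half-open interval [start, end) of CGM data to discard."""

    start: dt.datetime
    end: dt.datetime

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")

    def contains(self, ts: dt.datetime) -> bool:
        return self.start <= ts < self.end


@dataclass
class CleanedDay:
    """Samples of one day surviving exclusion; a subset of the raw day."""

    date: dt.date
    samples: list[GlucoseSample]

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth(day: DailySeries, window: int = 3) -> DailySeries:
    """Centered moving average over ``window`` consecutive samples.

    The default 3-sample window spans 15 minutes at nominal cadence —
    enough to knock down single-sample sensor error without flattening a
    meal excursion.  Edges average over the shorter available window, so a
    constant series is returned unchanged and interior points of a linear
    ramp are preserved.  Days with fewer than 3 samples pass through with a
    warning.
    """
    v = day.values
    n = len(v)
    if n < 3:
        log.warning("day %s has %d sample(s); skipping smoothing", day.date, n)
        return DailySeries(day.date, list(day.samples))
    half = window // 2
    sm = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm[i] = v[lo:hi].mean()
    return DailySeries(
        day.date, [GlucoseSample(s.ts, float(x)) for s, x in zip(day.samples, sm)]
    )


# ---------------------------------------------------------------------------
# peak geometry
# ---------------------------------------------------------------------------


def _plateaus(v: np.ndarray):
    """Yield (left_edge, right_edge, apex_index) for every strict local max.

    A run of equal values is one candidate; its apex is the run's center
    sample (the earlier of the two centers for even-length runs).  Runs
    touching the series boundary are not peaks.
    """
    n = len(v)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[j]:
            yield i, j, (i + j) // 2
        i = j + 1


def _neighboring_minima(v: np.ndarray, left_edge: int, right_edge: int) -> tuple[int, int]:
    """Indices of the local minima flanking the plateau [left_edge, right_edge]."""
    k = left_edge
    while k > 0 and v[k - 1] <= v[k]:
        k -= 1
    m = right_edge
    n = len(v)
    while m < n - 1 and v[m + 1] <= v[m]:
        m += 1
    return k, m


def _interp_width(
    hours: np.ndarray,
    v: np.ndarray,
    left_edge: int,
    right_edge: int,
    level: float,
    k: int,
    m: int,
) -> tuple[float, float, bool]:
    """Crossing times (fractional hours) of ``level`` on each flank.

    Scans outward from the apex plateau, bounded by the neighboring minima
    ``k`` (left) and ``m`` (right).  A flank that never reaches the level is
    clipped at its base; when that base is the first/last sample of the
    series (an edge-truncated peak) the truncation flag is set.
    """
    truncated = False
    t_left = hours[k]
    for i in range(left_edge - 1, k - 1, -1):
        if v[i] <= level:
            t_left = hours[i + 1] - (v[i + 1] - level) / (v[i + 1] - v[i]) * (
                hours[i + 1] - hours[i]
            )
            break
    else:
        truncated = truncated or k == 0
    t_right = hours[m]
    n = len(v)
    for i in range(right_edge + 1, m + 1):
        if v[i] <= level:
            t_right = hours[i - 1] + (v[i - 1] - level) / (v[i - 1] - v[i]) * (
                hours[i] - hours[i - 1]
            )
            break
    else:
        truncated = truncated or m == n - 1
    return t_left, t_right, truncated


def detect_peaks(
    day: DailySeries,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    rel_height: float = DEFAULT_REL_HEIGHT,
    height_base: str = "deeper",
) -> list[Peak]:
    """Detect every strict local maximum with height above the noise floor.

    Height is apex minus the deeper neighboring minimum (set
    ``height_base="higher"`` for the prominence-style base).  Width is
    measured by :func:`measure_width` at ``rel_height``.  A monotone day
    yields an empty list.
    """
    if height_base not in ("deeper", "higher"):
        raise ValueError("height_base must be 'deeper' or 'higher'")
    v = day.values
    hours = day.hours
    times = day.times
    peaks: list[Peak] = []
    for left, right, apex in _plateaus(v):
        k, m = _neighboring_minima(v, left, right)
        base = min(v[k], v[m]) if height_base == "deeper" else max(v[k], v[m])
        height = v[apex] - base
        if height < noise_floor:
            continue
        level = v[apex] - rel_height * height
        t_l, t_r, trunc = _interp_width(hours, v, left, right, level, k, m)
        peaks.append(
            Peak(
                t_apex=times[apex],
                apex_value=float(v[apex]),
                height=float(height),
                width=float(t_r - t_l),
                t_left_base=times[k],
                t_right_base=times[m],
                edge_truncated=trunc,
            )
        )
    return peaks


def measure_width(day: DailySeries, peak: Peak, rel_height: float = DEFAULT_REL_HEIGHT) -> float:
    """Width (hours) of ``peak`` at ``rel_height`` of its height.

    The two crossings of the level ``apex_value - rel_height * height`` are
    found by linear interpolation between bracketing samples, scanning
    outward from the apex plateau as far as the neighboring minima.  A flank
    on which the level is never crossed is clipped at its base; when that
    base is the first or last sample of the series the peak is edge-truncated
    (flagged on the peak when built through :func:`detect_peaks`).
    """
    if not 0 < rel_height <= 1:
        raise ValueError("rel_height must be in (0, 1]")
    v = day.values
    hours = day.hours
    times = day.times
    try:
        apex = times.index(peak.t_apex)
    except ValueError:
        raise ValueError(f"peak apex {peak.t_apex} not found in day {day.date}") from None
    left = apex
    while left > 0 and v[left - 1] == v[apex]:
        left -= 1
    right = apex
    while right < len(v) - 1 and v[right + 1] == v[apex]:
        right += 1
    k, m = _neighboring_minima(v, left, right)
    level = peak.apex_value - rel_height * peak.height
    t_l, t_r, _ = _interp_width(hours, v, left, right, level, k, m)
    return float(t_r - t_l)


# ---------------------------------------------------------------------------
# meal-likely flagging and exclusion windows
# ---------------------------------------------------------------------------


def flag_meal_peaks(peaks: list[Peak], q: float = DEFAULT_PERCENTILE) -> list[Peak]:
    """Peaks whose height OR width reaches the q-th percentile.

    Percentiles use linear interpolation between order statistics and the
    comparison is ``>=``, so a degenerate day (all heights equal) flags
    every peak on that axis.
    """
    if not peaks:
        return []
    heights = np.array([p.height for p in peaks])
    widths = np.array([p.width for p in peaks])
    h_thr = np.percentile(heights, q)
    w_thr = np.percentile(widths, q)
    return [p for p in peaks if p.height >= h_thr or p.width >= w_thr]


def _split_and_collect(
    start: dt.datetime, end: dt.datetime, acc: dict[dt.date, list[ExclusionWindow]]
) -> None:
    """Split [start, end) at the midnight following ``start``."""
    day_start = dt.datetime.combine(start.date(), dt.time())
    next_mid = day_start + dt.timedelta(days=1)
    if end <= next_mid:
        acc.setdefault(start.date(), []).append(ExclusionWindow(start, end))
    else:
        acc.setdefault(start.date(), []).append(ExclusionWindow(start, next_mid))
        acc.setdefault(next_mid.date(), []).append(ExclusionWindow(next_mid, end))


def _merge(windows: list[ExclusionWindow]) -> list[ExclusionWindow]:
    merged: list[ExclusionWindow] = []
    for w in sorted(windows, key=lambda w: (w.start, w.end)):
        if merged and w.start <= merged[-1].end:
            if w.end > merged[-1].end:
                merged[-1] = ExclusionWindow(merged[-1].start, w.end)
        else:
            merged.append(w)
    return merged


def build_exclusion_windows(
    flagged: list[Peak],
    pre_minutes: float = DEFAULT_PRE_MINUTES,
    post_minutes: float = DEFAULT_POST_MINUTES,
) -> dict[dt.date, list[ExclusionWindow]]:
    """Per-date exclusion windows ``[apex - pre, apex + post)`` for flagged peaks.

    A window crossing midnight is split, the overflow carried to the next
    calendar date; a window that would start before the apex date's 00:00 is
    clamped to 00:00 (only forward carry-over is performed).  Overlapping
    same-day windows are merged.
    """
    acc: dict[dt.date, list[ExclusionWindow]] = {}
    for p in flagged:
        start = p.t_apex - dt.timedelta(minutes=pre_minutes)
        end = p.t_apex + dt.timedelta(minutes=post_minutes)
        day_start = dt.datetime.combine(p.t_apex.date(), dt.time())
        if start < day_start:
            start = day_start
        _split_and_collect(start, end, acc)
    return {d: _merge(ws) for d, ws in sorted(acc.items())}


def meal_based_windows(
    meals: list[MealEvent], duration_minutes: float = MEAL_WINDOW_MINUTES
) -> dict[dt.date, list[ExclusionWindow]]:
    """Comparator-arm windows ``[meal, meal + 4h)``, midnight-split and merged."""
    acc: dict[dt.date, list[ExclusionWindow]] = {}
    for m in meals:
        _split_and_collect(m.ts, m.ts + dt.timedelta(minutes=duration_minutes), acc)
    return {d: _merge(ws) for d, ws in sorted(acc.items())}


def apply_exclusions(day: DailySeries | CleanedDay, windows: list[ExclusionWindow]) -> CleanedDay:
    """Drop samples falling inside any window; order is preserved."""
    kept = [s for s in day.samples if not any(w.contains(s.ts) for w in windows)]
    if day.samples and not kept:
        log.warning("all %d samples of %s excluded", len(day.samples), day.date)
    return CleanedDay(day.date, kept)


# ---------------------------------------------------------------------------
# whole-history pipeline
# ---------------------------------------------------------------------------


def clean_days(
    days: list[DailySeries],
    percentile: float = DEFAULT_PERCENTILE,
    rel_height: float = DEFAULT_REL_HEIGHT,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    pre_minutes: float = DEFAULT_PRE_MINUTES,
    post_minutes: float = DEFAULT_POST_MINUTES,
    global_percentile: bool = False,
    height_base: str = "deeper",
) -> tuple[list[CleanedDay], list[Peak], dict[dt.date, list[ExclusionWindow]]]:
    """Run the full meal-agnostic cleaning pipeline over a CGM history.

    Each day is smoothed and its peaks detected; the 95th-percentile
    height-or-width flag is applied per day (or pooled over all days with
    ``global_percentile``); exclusion windows are built with midnight
    carry-over and applied to the *raw* samples, so retained values are the
    original sensor readings.

    Returns (cleaned days, flagged peaks, per-date windows).
    """
    per_day_peaks = [
        detect_peaks(smooth(d), noise_floor=noise_floor, rel_height=rel_height, height_base=height_base)
        for d in days
    ]
    if global_percentile:
        flagged = flag_meal_peaks([p for ps in per_day_peaks for p in ps], percentile)
    else:
        flagged = [p for ps in per_day_peaks for p in flag_meal_peaks(ps, percentile)]
    windows = build_exclusion_windows(flagged, pre_minutes, post_minutes)
    log.debug(
        "flagged %d of %d peaks across %d days; %d window-days",
        len(flagged),
        sum(map(len, per_day_peaks)),
        len(days),
        len(windows),
    )
    cleaned = [apply_exclusions(d, windows.get(d.date, [])) for d in days]
    return cleaned, flagged, windows


def clean_days_with_meals(
    days: list[DailySeries],
    meals: list[MealEvent],
    duration_minutes: float = MEAL_WINDOW_MINUTES,
) -> tuple[list[CleanedDay], dict[dt.date, list[ExclusionWindow]]]:
    """Comparator arm: exclude the 4 hours following each announced meal."""
    windows = meal_based_windows(meals, duration_minutes)
    cleaned = [apply_exclusions(d, windows.get(d.date, [])) for d in days]
    return cleaned, windows
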