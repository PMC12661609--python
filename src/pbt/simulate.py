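"""Seedable synthetic CGM participants for end-to-end testing.

The generator emits what the cleaning pipeline assumes about real sensor
data: integer mg/dL readings on a 5-minute grid with random dropout, a
per-hour baseline drift standing in for a mis-set basal rate, skewed
(gamma-shaped) meal excursions peaking about an hour after the meal and
essentially gone within four, and additive Gaussian sensor noise.  Ground
truth (meal times, drift profile, per-sample meal influence) is returned
alongside so recovery can be scored without any external dataset.

The generative model, per sample at clock time t on some day::

    g(t) = baseline
         + d_h * (minutes into hour h) / 60          # drift, resets hourly
         + sum_meals response(t - t_meal)            # gamma-shaped bumps
         + Normal(0, noise_sd)

rounded to integer mg/dL and clipped to [40, 400].  Meal responses add
linearly when they overlap — a stated simplification, sufficient for
exercising the exclusion logic.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_formats import DailySeries, GlucoseSample, MealEvent, ValidationError

log = logging.getLogger(__name__)

#: Simulator clipping range, inside the CGM sensor reporting limits so that
#: generated files never trip boundary validation.
CLIP_LO, CLIP_HI = 40.0, 400.0

CADENCE_MINUTES = 5
#: Horizon after a meal during which samples are marked meal-influenced.
MEAL_INFLUENCE_HOURS = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic participant.

    Defaults follow the study conditions the package targets: 45 days of
    history, three daily meals (±20 min), excursion amplitude 80 ± 15
    mg/dL, gamma response peaking 1 h post-meal with ≥ 99% of its area
    inside 4 h, sensor noise SD 5 mg/dL, 2% dropout.
    """

    n_days: int = 45
    start_date: dt.date = dt.date(2023, 1, 1)
    baseline: float = 120.0
    drift_profile: tuple[float, ...] = (0.0,) * 24  # mg/dL per hour, one per hour
    meal_times: tuple[str, ...] = ("08:00", "13:00", "19:00")
    meal_jitter_sd_min: float = 20.0
    meal_amplitude_mean: float = 80.0
    meal_amplitude_sd: float = 15.0
    meal_shape: float = 5.0
    meal_scale_hours: float = 0.25
    response_kind: str = "gamma"  # gamma | lognormal
    noise_sd: float = 5.0
    dropout_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")
        if len(self.drift_profile) != 24:
            raise ValidationError("drift_profile must have exactly 24 entries")
        if self.response_kind not in ("gamma", "lognormal"):
            raise ValidationError("response_kind must be 'gamma' or 'lognormal'")
        if self.meal_shape <= 1 or self.meal_scale_hours <= 0:
            raise ValidationError("meal_shape must be > 1 and meal_scale_hours > 0")
        if self.meal_amplitude_mean <= 0 or self.meal_amplitude_sd < 0:
            raise ValidationError("meal amplitude mean must be > 0 and SD >= 0")
        if self.meal_jitter_sd_min < 0:
            raise ValidationError("meal_jitter_sd_min must be >= 0")
        for t in self.meal_times:
            _parse_clock(t)


def _parse_clock(text: str) -> dt.time:
    try:
        return dt.time.fromisoformat(text)
    except ValueError as exc:
        raise ValidationError(f"bad meal clock time {text!r}: {exc}") from None


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring recovery."""

    meals: list[MealEvent]
    drift_profile: tuple[float, ...]
    #: per emitted sample, True when its timestamp lies in [meal, meal + 4h)
    meal_influenced: dict[dt.date, list[bool]] = field(default_factory=dict)
    #: amplitude of each meal, aligned with ``meals``
    amplitudes: list[float] = field(default_factory=list)


def meal_response(
    dt_hours: float | np.ndarray,
    amplitude: float,
    shape: float = 5.0,
    scale: float = 0.25,
    kind: str = "gamma",
) -> float | np.ndarray:
    """Post-meal glucose excursion at ``dt_hours`` after the meal.

    A gamma (default) or log-normal density rescaled so its mode equals
    ``amplitude`` exactly: zero at the meal instant (shape > 1), a fast rise
    to the peak at ``(shape - 1) * scale`` hours, and a slower decay — under
    the default shape the response is below 1% of its amplitude beyond 4 h.
    Negative ``dt_hours`` (before the meal) gives 0.
    """
    t = np.asarray(dt_hours, dtype=float)
    if kind == "gamma":
        mode = (shape - 1.0) * scale
        dist = sps.gamma(a=shape, scale=scale)
    elif kind == "lognormal":
        # shape plays the log-SD role, scale = exp(mu)
        mode = scale * np.exp(-(shape**2))
        dist = sps.lognorm(s=shape, scale=scale)
    else:
        raise ValueError("kind must be 'gamma' or 'lognormal'")
    out = np.where(t >= 0, amplitude * dist.pdf(np.clip(t, 0, None)) / dist.pdf(mode), 0.0)
    return float(out) if np.isscalar(dt_hours) else out


def simulate(config: SimConfig) -> tuple[list[DailySeries], GroundTruth, list[MealEvent]]:
    """Generate one participant's CGM history and its ground truth.

    Returns (daily series, ground truth, meal events); the meal list is the
    ``meals.csv``-compatible annotation stream.  Identical configs (seed
    included) produce identical output, bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    minutes = np.arange(0, 24 * 60, CADENCE_MINUTES)
    minute_in_hour = minutes % 60
    hour_of_min = minutes // 60
    drift = np.array(config.drift_profile)[hour_of_min] * minute_in_hour / 60.0

    # draw all meals first so trace generation can see the previous day's
    meals: list[MealEvent] = []
    amplitudes: list[float] = []
    for d in range(config.n_days):
        date = config.start_date + dt.timedelta(days=d)
        for clock in config.meal_times:
            base = dt.datetime.combine(date, _parse_clock(clock))
            jitter = rng.normal(0.0, config.meal_jitter_sd_min)
            ts = base + dt.timedelta(minutes=float(jitter))
            ts = ts.replace(second=0, microsecond=0)
            amp = max(5.0, rng.normal(config.meal_amplitude_mean, config.meal_amplitude_sd))
            carbs = max(0.0, round(rng.normal(60.0, 15.0)))
            meals.append(MealEvent(ts, carbs))
            amplitudes.append(float(amp))
    meals_sorted = sorted(zip(meals, amplitudes), key=lambda p: p[0].ts)
    meals = [m for m, _ in meals_sorted]
    amplitudes = [a for _, a in meals_sorted]

    days: list[DailySeries] = []
    truth = GroundTruth(meals=meals, drift_profile=config.drift_profile, amplitudes=amplitudes)
    t0 = dt.datetime.combine(config.start_date, dt.time())
    meal_hours = np.array([(m.ts - t0).total_seconds() / 3600.0 for m in meals])

    for d in range(config.n_days):
        date = config.start_date + dt.timedelta(days=d)
        abs_hours = d * 24.0 + minutes / 60.0
        values = config.baseline + drift.copy()
        # responses from meals of this day and the previous one (tails)
        for mh, amp in zip(meal_hours, amplitudes):
            if d * 24.0 - 24.0 <= mh < (d + 1) * 24.0:
                values = values + meal_response(
                    abs_hours - mh,
                    amp,
                    config.meal_shape,
                    config.meal_scale_hours,
                    config.response_kind,
                )
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=len(values))
        values = np.clip(np.rint(values), CLIP_LO, CLIP_HI)
        keep = rng.random(len(values)) >= config.dropout_prob

        samples: list[GlucoseSample] = []
        influenced: list[bool] = []
        midnight = dt.datetime.combine(date, dt.time())
        horizon = dt.timedelta(hours=MEAL_INFLUENCE_HOURS)
        nearby = [
            m for m in meals if midnight - horizon <= m.ts < midnight + dt.timedelta(days=1)
        ]
        for minute, value, k in zip(minutes, values, keep):
            if not k:
                continue
            ts = midnight + dt.timedelta(minutes=int(minute))
            samples.append(GlucoseSample(ts, float(value)))
            influenced.append(any(m.ts <= ts < m.ts + horizon for m in nearby))
        if not samples:
            log.warning("day %s lost all samples to dropout; omitted", date)
            continue
        days.append(DailySeries(date, samples))
        truth.meal_influenced[date] = influenced
    return days, truth, meals
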