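"""Reading and writing the CSV/JSON event tables and result files.

The on-disk dialect is deliberately small: every input is a flat CSV with an
ISO 8601 local-clock timestamp column, every tabular result is a CSV, and
every nested result is JSON.  Timestamps carry no timezone — the algorithm
reasons in the patient's wall-clock day, so a DST-shifted day still maps onto
the 00:00–23:59 grid by clock label.

Validation happens at this boundary: glucose outside the CGM sensor reporting
range (20–600 mg/dL), duplicate timestamps, negative doses and malformed
rows are rejected loudly rather than silently repaired.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: CGM sensor reporting range, mg/dL.
GLUCOSE_MIN = 20.0
GLUCOSE_MAX = 600.0

TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class PBTError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PBTError):
    """A file could not be parsed (malformed timestamp or number)."""


class ValidationError(PBTError):
    """Parsed data violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GlucoseSample:
    """One CGM reading: local timestamp and glucose in mg/dL."""

    ts: dt.datetime
    value: float


@dataclass
class DailySeries:
    """All CGM samples of one participant on one calendar date, ordered.

    Nominal cadence is 5 minutes; gaps are permitted, duplicates are not.
    """

    date: dt.date
    samples: list[GlucoseSample]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.samples], dtype=float)

    @property
    def times(self) -> list[dt.datetime]:
        return [s.ts for s in self.samples]

    @property
    def hours(self) -> np.ndarray:
        """Sample times as fractional hours since this date's midnight."""
        midnight = dt.datetime.combine(self.date, dt.time())
        return np.array(
            [(s.ts - midnight).total_seconds() / 3600.0 for s in self.samples]
        )


@dataclass(frozen=True)
class MealEvent:
    ts: dt.datetime
    carbs: float | None = None  # grams; annotations may omit the amount


@dataclass(frozen=True)
class BolusEvent:
    ts: dt.datetime
    dose: float  # insulin units, > 0


@dataclass(frozen=True)
class BasalRecord:
    ts_start: dt.datetime
    rate: float  # insulin units per hour, >= 0


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_timestamps(raw: pd.Series, path: Path | str, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=TS_FORMAT, errors="coerce")
    bad = parsed.isna() | raw.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: line {i + 2}: malformed timestamp {raw.iloc[i]!r} "
            f"in column {column!r} (expected {TS_FORMAT})"
        )
    return parsed


def _parse_numeric(
    raw: pd.Series, path: Path | str, column: str, allow_blank: bool = False
) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & ~(raw.isna() if allow_blank else False)
    if isinstance(bad, pd.Series) and bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: line {i + 2}: non-numeric value {raw.iloc[i]!r} "
            f"in column {column!r}"
        )
    return vals


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_cgm(path: str | Path) -> list[DailySeries]:
    """Read ``cgm.csv`` (header ``ts,glucose_mgdl``) into per-date series.

    Returns one :class:`DailySeries` per calendar date present, sorted by
    date, samples sorted by timestamp.  Never returns an empty day.

    Raises
    ------
    ParseError
        Malformed timestamp or glucose value (the message names the line).
    ValidationError
        Glucose outside [20, 600] mg/dL, or duplicate timestamps.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("ts", "glucose_mgdl"), path)
    ts = _parse_timestamps(df["ts"], path, "ts")
    glucose = _parse_numeric(df["glucose_mgdl"], path, "glucose_mgdl")

    out_of_range = (glucose < GLUCOSE_MIN) | (glucose > GLUCOSE_MAX)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {i + 2}: glucose {glucose.iloc[i]} mg/dL outside "
            f"sensor range [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}]"
        )

    order = np.argsort(ts.to_numpy(), kind="stable")
    ts_sorted = ts.to_numpy()[order]
    if len(ts_sorted) > 1 and (ts_sorted[1:] == ts_sorted[:-1]).any():
        dup = pd.Timestamp(ts_sorted[np.flatnonzero(ts_sorted[1:] == ts_sorted[:-1])[0]])
        raise ValidationError(f"{path}: duplicate CGM timestamp {dup.isoformat()}")

    days: dict[dt.date, list[GlucoseSample]] = {}
    for idx in order:
        t = ts.iloc[idx].to_pydatetime()
        days.setdefault(t.date(), []).append(GlucoseSample(t, float(glucose.iloc[idx])))
    return [DailySeries(d, samples) for d, samples in sorted(days.items())]


_EVENT_SCHEMAS = {
    "meal": ("ts", "carbs_g"),
    "bolus": ("ts", "dose_u"),
    "basal": ("ts_start", "rate_uph"),
}


def read_events(path: str | Path, kind: str) -> list[MealEvent | BolusEvent | BasalRecord]:
    """Read a ``meals.csv`` / ``bolus.csv`` / ``basal.csv`` event table.

    Events come back sorted by timestamp.  ``kind`` must be one of
    ``{"meal", "bolus", "basal"}`` (anything else is a usage error).
    """
    if kind not in _EVENT_SCHEMAS:
        raise ValueError(f"unknown event kind {kind!r}; expected one of {sorted(_EVENT_SCHEMAS)}")
    ts_col, val_col = _EVENT_SCHEMAS[kind]
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, (ts_col, val_col), path)
    if df.empty:
        return []
    ts = _parse_timestamps(df[ts_col], path, ts_col)
    vals = _parse_numeric(df[val_col], path, val_col, allow_blank=(kind == "meal"))

    events: list[Any] = []
    for i in range(len(df)):
        t = ts.iloc[i].to_pydatetime()
        v = vals.iloc[i]
        v = None if pd.isna(v) else float(v)
        if kind == "meal":
            if v is not None and v < 0:
                raise ValidationError(f"{path}: line {i + 2}: negative carbs {v}")
            events.append(MealEvent(t, v))
        elif kind == "bolus":
            if v is None or v <= 0:
                raise ValidationError(f"{path}: line {i + 2}: bolus dose must be > 0, got {v}")
            events.append(BolusEvent(t, v))
        else:
            if v is None or v < 0:
                raise ValidationError(f"{path}: line {i + 2}: basal rate must be >= 0, got {v}")
            events.append(BasalRecord(t, v))

    events.sort(key=lambda e: e.ts_start if kind == "basal" else e.ts)
    if kind == "basal":
        starts = [e.ts_start for e in events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError(f"{path}: basal records must have strictly increasing ts_start")
    return events


# ---------------------------------------------------------------------------
# CGM / cleaned-trace writers
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Full-precision decimal text; integers stay integral."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_cgm(days: Iterable[DailySeries], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ts", "glucose_mgdl"])
        for day in days:
            for s in day.samples:
                w.writerow([s.ts.strftime(TS_FORMAT), _fmt(s.value)])


def write_meals(meals: Iterable[MealEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ts", "carbs_g"])
        for m in meals:
            w.writerow([m.ts.strftime(TS_FORMAT), "" if m.carbs is None else _fmt(m.carbs)])


def write_cleaned(days: Iterable[DailySeries], excluded: set[dt.datetime], path: str | Path) -> None:
    """Write the cgm dialect plus an ``excluded`` 0/1 column.

    Every raw sample appears in the file, so the conservation identity
    |raw| = |kept| + |excluded| is auditable from the file alone.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ts", "glucose_mgdl", "excluded"])
        for day in days:
            for s in day.samples:
                w.writerow([s.ts.strftime(TS_FORMAT), _fmt(s.value), int(s.ts in excluded)])


def read_cleaned(path: str | Path):
    """Read ``cleaned.csv`` back into retained-sample days (``CleanedDay``)."""
    from .peaks import CleanedDay  # local import: peaks depends on this module

    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("ts", "glucose_mgdl", "excluded"), path)
    ts = _parse_timestamps(df["ts"], path, "ts")
    glucose = _parse_numeric(df["glucose_mgdl"], path, "glucose_mgdl")
    excl = _parse_numeric(df["excluded"], path, "excluded")
    days: dict[dt.date, list[GlucoseSample]] = {}
    for i in range(len(df)):
        if int(excl.iloc[i]):
            continue
        t = ts.iloc[i].to_pydatetime()
        days.setdefault(t.date(), []).append(GlucoseSample(t, float(glucose.iloc[i])))
    return [CleanedDay(d, sorted(s)) for d, s in sorted(days.items())]


# ---------------------------------------------------------------------------
# result writers / readers
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = (
    "hour",
    "median",
    "q1",
    "q3",
    "whisker_lo",
    "whisker_hi",
    "n",
    "reliability",
    "outliers",
)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (dt.datetime, dt.date)):
        return obj.isoformat()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def write_results(results: Any, path: str | Path) -> None:
    """Write a result object to ``path``.

    Tabular results (a list of hourly distributions or interval
    classifications) become CSV; single result records and nested dicts
    become JSON tagged with ``_type`` so a round-trip read restores the
    original values exactly.  An empty list yields a header-only
    hourly-profile CSV.
    """
    from .profile import HourlyDistribution
    from .stats import IntervalClassification

    if isinstance(results, list) and (
        not results or isinstance(results[0], HourlyDistribution)
    ):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(PROFILE_COLUMNS)
            for d in results:
                w.writerow(
                    [
                        d.hour,
                        *["" if v is None else _fmt(v) for v in (d.median, d.q1, d.q3, d.whisker_lo, d.whisker_hi)],
                        d.n,
                        d.reliability,
                        ";".join(_fmt(o) for o in d.outliers),
                    ]
                )
        return

    if isinstance(results, list) and isinstance(results[0], IntervalClassification):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant", "hour", "category", "median_delta"])
            for c in results:
                w.writerow([c.participant, c.hour, c.category, _fmt(c.median_delta)])
        return

    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        payload = dataclasses.asdict(results)
        payload["_type"] = type(results).__name__
    elif isinstance(results, dict):
        payload = {
            k: (
                {**dataclasses.asdict(v), "_type": type(v).__name__}
                if dataclasses.is_dataclass(v) and not isinstance(v, type)
                else v
            )
            for k, v in results.items()
        }
    else:
        raise TypeError(f"do not know how to write results of type {type(results).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def read_profile(path: str | Path):
    """Read ``hourly_profile.csv`` back into hourly distributions."""
    from .profile import HourlyDistribution

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                HourlyDistribution(
                    hour=int(row["hour"]),
                    median=_opt_float(row["median"]),
                    q1=_opt_float(row["q1"]),
                    q3=_opt_float(row["q3"]),
                    whisker_lo=_opt_float(row["whisker_lo"]),
                    whisker_hi=_opt_float(row["whisker_hi"]),
                    n=int(row["n"]),
                    reliability=row["reliability"],
                    outliers=[float(x) for x in row["outliers"].split(";") if x],
                )
            )
    return out


def read_result_json(path: str | Path) -> Any:
    """Read a JSON result written by :func:`write_results`.

    Objects tagged with ``_type`` are reconstructed as their dataclass.
    """
    from . import stats as _stats

    def revive(d: dict) -> Any:
        name = d.pop("_type", None)
        if name is None:
            return d
        cls = getattr(_stats, name)
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict) and "_type" in payload:
        return revive(payload)
    if isinstance(payload, dict):
        return {k: revive(v) if isinstance(v, dict) and "_type" in v else v for k, v in payload.items()}
    return payload
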