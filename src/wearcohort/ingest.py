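"""Parse intraday wearable exports and assess per-day data completeness.

A subject's export consists of three comma-delimited files with header rows
and ISO-8601 local timestamps (no timezone arithmetic is performed; a
single-site study's wall clock is taken at face value):

* ``steps_intraday.csv`` — ``timestamp,steps``: step counts on a 15-minute
  grid (start minute in {0, 15, 30, 45}).
* ``hr_intraday.csv`` — ``timestamp,bpm,confidence``: heart rate at roughly
  5-minute cadence with a device confidence code; ``confidence == -1`` marks
  a reading taken while the device was not (properly) worn, which is retained
  in the timeline but excluded from every metric.
* ``sleep.csv`` — ``start,end``: one row per sleep session.

The merged timeline annotates each HR reading with the step count of its
enclosing 15-minute interval (half-open ``[start, start + 15 min)``), and the
day ledger classifies each calendar day as *complete* when at least 20 clock
hours contain a valid-confidence HR reading and intraday step data exist for
that day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STEP_GRID_MINUTES = 15
VALID_HOURS_COMPLETE = 20  # clock hours with valid HR needed for a complete day


class ParseError(ValueError):
    """Raised when an export file violates its schema; names the offending row."""


@dataclass(frozen=True)
class DayLedger:
    """Completeness record for one calendar day of one subject."""

    day: pd.Timestamp
    valid_hours: int
    has_intraday_steps: bool
    complete: bool


def _read_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header must be {','.join(columns)}")
    return df


def _parse_timestamps(raw: pd.Series, path, column: str) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = ts.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: unparseable {column} {raw.iloc[row]!r}")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: empty {column}")
    return ts


def read_intraday_steps(path) -> pd.DataFrame:
    """Read 15-minute step intervals; returns columns ``start`` and ``steps``.

    Rows are sorted by ``start``. Negative counts, off-grid timestamps and
    duplicate interval starts raise :class:`ParseError` naming the row.
    """
    df = _read_csv(path, ("timestamp", "steps"))
    if df.empty:
        logger.warning("%s: no step intervals", path)
        return pd.DataFrame({"start": pd.Series(dtype="datetime64[ns]"), "steps": pd.Series(dtype=int)})
    start = _parse_timestamps(df["timestamp"], path, "timestamp")
    steps = pd.to_numeric(df["steps"], errors="coerce")
    if steps.isna().any():
        row = int(np.flatnonzero(steps.isna().to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: unparseable step count {df['steps'].iloc[row]!r}")
    if (steps < 0).any():
        row = int(np.flatnonzero((steps < 0).to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: negative step count {steps.iloc[row]}")
    off_grid = (start.dt.minute % STEP_GRID_MINUTES != 0) | (start.dt.second != 0)
    if off_grid.any():
        row = int(np.flatnonzero(off_grid.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: timestamp {start.iloc[row]} not on the 15-minute grid")
    if start.duplicated().any():
        row = int(np.flatnonzero(start.duplicated().to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: duplicate interval start {start.iloc[row]}")
    out = pd.DataFrame({"start": start, "steps": steps.astype(int)})
    return out.sort_values("start", ignore_index=True)


def read_intraday_hr(path) -> pd.DataFrame:
    """Read HR points; returns columns ``timestamp``, ``hr_bpm``, ``confidence``.

    Readings with ``confidence == -1`` are retained (they drive the
    completeness accounting) but flagged invalid. A non-positive heart rate
    with any other confidence code is a parse error.
    """
    df = _read_csv(path, ("timestamp", "bpm", "confidence"))
    if df.empty:
        logger.warning("%s: no HR points", path)
        return pd.DataFrame(
            {
                "timestamp": pd.Series(dtype="datetime64[ns]"),
                "hr_bpm": pd.Series(dtype=float),
                "confidence": pd.Series(dtype=int),
            }
        )
    ts = _parse_timestamps(df["timestamp"], path, "timestamp")
    hr = pd.to_numeric(df["bpm"], errors="coerce")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    for name, col in (("bpm", hr), ("confidence", conf)):
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ParseError(f"{path}: row {row + 2}: unparseable {name} {df[name].iloc[row]!r}")
    bad_hr = (hr <= 0) & (conf != -1)
    if bad_hr.any():
        row = int(np.flatnonzero(bad_hr.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: non-positive HR {hr.iloc[row]} with confidence {conf.iloc[row]}")
    out = pd.DataFrame({"timestamp": ts, "hr_bpm": hr.astype(float), "confidence": conf.astype(int)})
    return out.sort_values("timestamp", ignore_index=True)


def read_sleep_sessions(path) -> pd.DataFrame:
    """Read sleep sessions; returns columns ``start`` and ``end``.

    Sessions must end after they start and last under 24 h. Overlapping
    sessions are accepted with a warning; per-day duration sums use raw
    session lengths (no union).
    """
    df = _read_csv(path, ("start", "end"))
    if df.empty:
        logger.warning("%s: no sleep sessions", path)
        return pd.DataFrame(
            {"start": pd.Series(dtype="datetime64[ns]"), "end": pd.Series(dtype="datetime64[ns]")}
        )
    start = _parse_timestamps(df["start"], path, "start")
    end = _parse_timestamps(df["end"], path, "end")
    bad = end <= start
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: session end {end.iloc[row]} not after start {start.iloc[row]}")
    too_long = (end - start) >= pd.Timedelta(hours=24)
    if too_long.any():
        row = int(np.flatnonzero(too_long.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: session of 24 h or longer")
    out = pd.DataFrame({"start": start, "end": end}).sort_values("start", ignore_index=True)
    if (out["start"].iloc[1:].to_numpy() < out["end"].iloc[:-1].to_numpy()).any():
        logger.warning("%s: overlapping sleep sessions retained", path)
    return out


def merge_by_time(hr: pd.DataFrame, steps: pd.DataFrame) -> pd.DataFrame:
    """Annotate each HR point with the step count of its enclosing interval.

    Membership is half-open: a reading at exactly an interval start belongs to
    that interval. No HR point is dropped; points with no covering interval
    get a missing ``matched_steps`` (nullable integer).
    """
    out = hr.copy()
    if hr.empty:
        out["matched_steps"] = pd.Series(dtype="Int64")
        return out
    bin_start = out["timestamp"].dt.floor(f"{STEP_GRID_MINUTES}min")
    lookup = steps.set_index("start")["steps"] if not steps.empty else pd.Series(dtype=int)
    out["matched_steps"] = bin_start.map(lookup).astype("Int64")
    return out


def build_day_ledger(
    timeline: pd.DataFrame,
    steps: pd.DataFrame,
    *,
    min_valid_hours: int = VALID_HOURS_COMPLETE,
    min_points_per_hour: int = 1,
) -> pd.DataFrame:
    """Classify each calendar day present in either stream as complete or not.

    A clock hour is *valid* when it contains at least ``min_points_per_hour``
    HR readings with confidence != -1; a day is *complete* when it has at
    least ``min_valid_hours`` valid hours and at least one step interval.
    Returns columns ``day``, ``valid_hours``, ``has_intraday_steps``,
    ``complete``.
    """
    hr_days = timeline["timestamp"].dt.normalize() if not timeline.empty else pd.Series(dtype="datetime64[ns]")
    step_days = steps["start"].dt.normalize() if not steps.empty else pd.Series(dtype="datetime64[ns]")
    all_days = pd.Index(hr_days).union(pd.Index(step_days)).unique().sort_values()

    valid = timeline[timeline["confidence"] != -1] if not timeline.empty else timeline
    if valid is not None and not valid.empty:
        per_hour = valid.groupby([valid["timestamp"].dt.normalize(), valid["timestamp"].dt.hour]).size()
        valid_hours = (per_hour >= min_points_per_hour).groupby(level=0).sum()
    else:
        valid_hours = pd.Series(dtype=int)
    step_day_set = set(step_days)

    rows = []
    for day in all_days:
        vh = int(valid_hours.get(day, 0))
        has_steps = day in step_day_set
        rows.append(
            {
                "day": day,
                "valid_hours": vh,
                "has_intraday_steps": has_steps,
                "complete": vh >= min_valid_hours and has_steps,
            }
        )
    return pd.DataFrame(rows, columns=["day", "valid_hours", "has_intraday_steps", "complete"])


def complete_days(ledger: pd.DataFrame) -> pd.DatetimeIndex:
    """Calendar days flagged complete in a ledger."""
    if ledger.empty:
        return pd.DatetimeIndex([])
    return pd.DatetimeIndex(ledger.loc[ledger["complete"], "day"])
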