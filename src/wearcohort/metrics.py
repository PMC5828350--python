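"""Per-subject wearable summary metrics.

Resting heart rate is the mean of valid-confidence HR readings whose
enclosing 15-minute interval recorded at most 100 steps, pooled across all
data-complete days. Day and night HR apply the same criteria inside the
2–4 PM and 2–4 AM clock windows. Average daily steps come either from
summing intervals over complete days (``daily_steps``) or from the mean
HR-matched interval count scaled by 96 intervals/day (``daily_steps_alt``).
Sleep metrics summarise session duration and clock timing; subjects whose
sleep metrics fall outside cohort mean ± 2 SD are excluded from sleep
analyses by :func:`two_sd_filter`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import complete_days

logger = logging.getLogger(__name__)

RESTING_STEP_MAX = 100          # steps in the enclosing 15-min interval
DAY_WINDOW = (14.0, 16.0)       # 2 PM – 4 PM
NIGHT_WINDOW = (2.0, 4.0)       # 2 AM – 4 AM
SLEEP_ONSET_WINDOW = (19.0, 4.0)  # sessions starting 7 PM – 4 AM define sleep hour
HR_PLAUSIBLE = (30.0, 220.0)    # physiological bounds; readings outside are dropped
INTERVALS_PER_DAY = 96


@dataclass
class SubjectMetrics:
    """Wearable summary for one subject; ``None`` marks an absent metric."""

    subject_id: str
    resting_hr: float | None = None
    day_hr: float | None = None
    night_hr: float | None = None
    daily_steps: float | None = None
    daily_steps_alt: float | None = None
    sleep_duration: float | None = None   # minutes/day
    sleep_hour: float | None = None       # clock hours mod 24
    wake_hour: float | None = None        # clock hours
    n_complete_days: int = 0
    reasons: dict[str, str] = field(default_factory=dict)


def _qualifying_points(timeline: pd.DataFrame, days: pd.DatetimeIndex) -> pd.DataFrame:
    """Valid-confidence, step-matched, resting points on complete days."""
    if timeline.empty or len(days) == 0:
        return timeline.iloc[0:0]
    pts = timeline[timeline["timestamp"].dt.normalize().isin(days)]
    pts = pts[(pts["confidence"] != -1) & pts["matched_steps"].notna()]
    implausible = (pts["hr_bpm"] <= HR_PLAUSIBLE[0]) | (pts["hr_bpm"] >= HR_PLAUSIBLE[1])
    if implausible.any():
        logger.warning("dropping %d physiologically implausible HR readings", int(implausible.sum()))
        pts = pts[~implausible]
    return pts[pts["matched_steps"] <= RESTING_STEP_MAX]


def resting_hr(timeline: pd.DataFrame, ledger: pd.DataFrame) -> float | None:
    """Mean HR over valid resting points on complete days; None if no points."""
    pts = _qualifying_points(timeline, complete_days(ledger))
    if pts.empty:
        return None
    return float(pts["hr_bpm"].mean())


def windowed_hr(timeline: pd.DataFrame, ledger: pd.DataFrame, window: tuple[float, float]) -> float | None:
    """Resting-HR criteria restricted to a half-open clock window [lo, hi).

    Windows wrapping midnight (lo > hi) are supported.
    """
    pts = _qualifying_points(timeline, complete_days(ledger))
    if pts.empty:
        return None
    hour = pts["timestamp"].dt.hour + pts["timestamp"].dt.minute / 60.0
    lo, hi = window
    mask = (hour >= lo) & (hour < hi) if lo <= hi else (hour >= lo) | (hour < hi)
    pts = pts[mask]
    if pts.empty:
        return None
    return float(pts["hr_bpm"].mean())


def daily_steps(steps: pd.DataFrame, ledger: pd.DataFrame) -> float | None:
    """Mean over complete days of the within-day sum of interval steps."""
    days = complete_days(ledger)
    if steps.empty or len(days) == 0:
        return None
    on_complete = steps[steps["start"].dt.normalize().isin(days)]
    if on_complete.empty:
        return None
    per_day = on_complete.groupby(on_complete["start"].dt.normalize())["steps"].sum()
    # complete days with step data but zero-filled elsewhere still count as 0
    per_day = per_day.reindex(days, fill_value=0)
    return float(per_day.mean())


def daily_steps_alt(timeline: pd.DataFrame, ledger: pd.DataFrame, *, per_point: bool = False) -> float | None:
    """Estimate daily steps as 96 × the mean HR-matched interval step count.

    By default each enclosing 15-minute interval containing at least one
    valid HR reading contributes once, so intervals with several HR reads are
    not over-weighted; ``per_point=True`` averages over HR points instead.
    """
    days = complete_days(ledger)
    if timeline.empty or len(days) == 0:
        return None
    pts = timeline[timeline["timestamp"].dt.normalize().isin(days)]
    pts = pts[(pts["confidence"] != -1) & pts["matched_steps"].notna()]
    if pts.empty:
        return None
    if per_point:
        mean_steps = float(pts["matched_steps"].astype(float).mean())
    else:
        interval = pts["timestamp"].dt.floor("15min")
        mean_steps = float(pts.groupby(interval)["matched_steps"].first().astype(float).mean())
    return mean_steps * INTERVALS_PER_DAY


def sleep_summary(
    sessions: pd.DataFrame, ledger: pd.DataFrame
) -> tuple[float | None, float | None, float | None]:
    """(mean daily sleep minutes, mean sleep-onset hour, mean wake hour).

    Sessions are attributed to the calendar day they start on; the daily
    duration is the raw sum of that day's session lengths, averaged over
    complete days. Sleep hour averages onset clock hours of sessions starting
    between 7 PM and 4 AM, mapping post-midnight starts +24 h before the mean
    and reporting the result modulo 24. Wake hour is the plain mean of
    session end clock hours.
    """
    days = complete_days(ledger)
    if sessions.empty or len(days) == 0:
        return None, None, None
    on_complete = sessions[sessions["start"].dt.normalize().isin(days)]
    if on_complete.empty:
        return None, None, None

    dur = (on_complete["end"] - on_complete["start"]).dt.total_seconds() / 60.0
    per_day = dur.groupby(on_complete["start"].dt.normalize()).sum()
    sleep_duration = float(per_day.mean())

    start_hour = on_complete["start"].dt.hour + on_complete["start"].dt.minute / 60.0
    lo, hi = SLEEP_ONSET_WINDOW
    onset = start_hour[(start_hour >= lo) | (start_hour <= hi)]
    if onset.empty:
        sleep_hour = None
    else:
        sleep_hour = float(np.where(onset < hi + 1e-9, onset + 24.0, onset).mean() % 24.0)

    end_hour = on_complete["end"].dt.hour + on_complete["end"].dt.minute / 60.0
    wake_hour = float(end_hour.mean())
    return sleep_duration, sleep_hour, wake_hour


def subject_metrics(
    subject_id: str,
    timeline: pd.DataFrame,
    steps: pd.DataFrame,
    sessions: pd.DataFrame,
    ledger: pd.DataFrame,
) -> SubjectMetrics:
    """Derive the full wearable summary for one subject."""
    m = SubjectMetrics(subject_id=subject_id, n_complete_days=len(complete_days(ledger)))
    if m.n_complete_days == 0:
        m.reasons["all"] = "no complete tracking days"
        return m
    m.resting_hr = resting_hr(timeline, ledger)
    if m.resting_hr is None:
        m.reasons["resting_hr"] = "no valid resting points"
    m.day_hr = windowed_hr(timeline, ledger, DAY_WINDOW)
    m.night_hr = windowed_hr(timeline, ledger, NIGHT_WINDOW)
    m.daily_steps = daily_steps(steps, ledger)
    m.daily_steps_alt = daily_steps_alt(timeline, ledger)
    m.sleep_duration, m.sleep_hour, m.wake_hour = sleep_summary(sessions, ledger)
    return m


def metrics_table(metrics: list[SubjectMetrics]) -> pd.DataFrame:
    """One row per subject, columns as in :class:`SubjectMetrics`."""
    cols = [
        "subject_id", "resting_hr", "day_hr", "night_hr", "daily_steps",
        "daily_steps_alt", "sleep_duration", "sleep_hour", "wake_hour",
        "n_complete_days",
    ]
    rows = [{c: getattr(m, c) for c in cols} | {"reasons": ";".join(f"{k}:{v}" for k, v in m.reasons.items())} for m in metrics]
    return pd.DataFrame(rows, columns=cols + ["reasons"])


def sleep_hour_continuous(sleep_hour: pd.Series) -> pd.Series:
    """Map mod-24 sleep-onset hours onto a continuous evening scale.

    Onsets after midnight (reported as small clock hours) are shifted +24 so
    that cohort means and SDs are not split across the midnight wrap; used
    before 2-SD filtering and between-cluster comparisons.
    """
    s = sleep_hour.astype(float)
    return s.where(s >= 12.0, s + 24.0)


def two_sd_filter(values: pd.DataFrame) -> pd.Series:
    """Retain subjects whose every supplied metric lies within mean ± 2 SD.

    Cohort mean and SD are computed over non-missing values per metric; a
    missing value never excludes a subject, and a zero-variance metric
    retains everyone. Requires at least 3 subjects.
    """
    if len(values) < 3:
        raise ValueError("two_sd_filter needs at least 3 subjects")
    keep = pd.Series(True, index=values.index)
    for col in values.columns:
        v = values[col].astype(float)
        mu, sd = v.mean(), v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        out_of_band = (v - mu).abs() > 2 * sd
        keep &= ~out_of_band.fillna(False)
    return keep


def correlate_spearman(x, y) -> float | None:
    """Spearman rank correlation (average ranks for ties) over paired non-missing values."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        return None
    r, _ = stats.spearmanr(x[ok], y[ok])
    return float(r)
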