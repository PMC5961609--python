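"""Per-dwelling winter thermal-exposure metrics against the 18 °C criterion.

Four outcome variables are derived per dwelling from the cleaned, windowed
logger readings:

(a) ``mean_winter_temperature`` — arithmetic mean of all retained readings,
    per room.
(b) ``pct_days_meeting`` — percentage of monitored days on which at least a
    configured fraction of the day's readings (default 68/72 ≈ 94.4%) are at
    or above the threshold. A percentage rather than a count, since homes
    differ in how many days were monitored.
(c) ``mean_hours_per_day`` — average hours per day at or above the
    threshold, counted in consecutive-reading segments: a 20-minute segment
    qualifies when both of its readings meet the threshold. Days run
    midnight to midnight; the segment ending at the next midnight is
    attributed to the earlier day.
(d) ``mean_night_hours`` — as (c) but restricted to the 20:00–08:00 night
    window and to the bedroom; at most 12 hours per night.

All comparisons with the threshold are inclusive ("at 18 °C or above"), as
is the day-fraction boundary: a day with exactly 68 of 72 readings at the
threshold meets the criterion.

Segments are only formed by readings exactly one cadence apart (±1 minute);
gaps break segments rather than being interpolated. Under the default
terminal-day policy the last monitored day of each month block is excluded
from the hour metrics (c)/(d), since its final cross-midnight segment has no
subsequent day; ``terminal_day_policy="keep_day"`` retains those days with
whatever segments they have.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import time
from typing import Iterable

import numpy as np
import pandas as pd

from coldhomes.io import ROOMS, TemperatureSeries

__all__ = [
    "MetricConfig",
    "mean_winter_temperature",
    "day_fraction_at_threshold",
    "pct_days_meeting",
    "mean_hours_per_day",
    "mean_night_hours",
    "compute_dwelling_metrics",
    "share_meeting_at_night",
]

# absorbs float error in fraction comparisons without affecting 20-min data
_FRAC_EPS = 1e-12


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds and conventions for the derived outcome variables."""

    threshold_c: float = 18.0
    day_fraction: float = 68 / 72        # ≈ 94.4% of the day's readings
    night_start: time = time(20, 0)
    night_end: time = time(8, 0)         # next day; window crosses midnight
    min_readings_per_day: int = 36       # 50% coverage for a day to be eligible
    cadence_minutes: int = 20
    terminal_day_policy: str = "exclude_day"  # or "keep_day"

    def __post_init__(self) -> None:
        if not 0 < self.day_fraction <= 1:
            raise ValueError("day_fraction must be in (0, 1]")
        if not np.isfinite(self.threshold_c):
            raise ValueError("threshold_c must be finite")
        if self.terminal_day_policy not in ("exclude_day", "keep_day"):
            raise ValueError("terminal_day_policy must be 'exclude_day' or 'keep_day'")
        if self.cadence_minutes <= 0 or 1440 % self.cadence_minutes != 0:
            raise ValueError("cadence_minutes must divide 1440")

    def with_(self, **kwargs) -> "MetricConfig":
        return replace(self, **kwargs)


def mean_winter_temperature(series: TemperatureSeries) -> float:
    """Unweighted mean of all retained readings; NaN for an empty series."""
    if len(series) == 0:
        return float("nan")
    return float(series.temps.mean())


def day_fraction_at_threshold(
    day_readings: np.ndarray, threshold_c: float = 18.0
) -> float:
    """Fraction of a day's readings at or above the threshold (inclusive)."""
    day_readings = np.asarray(day_readings, dtype=float)
    if day_readings.size == 0:
        return float("nan")
    return float((day_readings >= threshold_c).mean())


def _per_day(series: TemperatureSeries, cfg: MetricConfig):
    """Unique monitored dates with reading counts and at-threshold counts."""
    dates = series.timestamps.astype("datetime64[D]")
    uniq, idx, counts = np.unique(dates, return_index=True, return_counts=True)
    ok = (series.temps >= cfg.threshold_c).astype(np.int64)
    n_ok = np.add.reduceat(ok, idx)
    return uniq, counts, n_ok


def n_days_monitored(series: TemperatureSeries, cfg: MetricConfig) -> int:
    """Number of eligible monitored days (≥ min_readings_per_day readings)."""
    if len(series) == 0:
        return 0
    _, counts, _ = _per_day(series, cfg)
    return int((counts >= cfg.min_readings_per_day).sum())


def pct_days_meeting(series: TemperatureSeries, cfg: MetricConfig = MetricConfig()) -> float:
    """Percentage of eligible days meeting the day-fraction criterion.

    A day meets the criterion when its fraction of at-or-above-threshold
    readings is at least ``cfg.day_fraction`` (inclusive boundary). Days
    with fewer than ``min_readings_per_day`` readings are excluded from the
    denominator. NaN when no day is eligible.
    """
    if len(series) == 0:
        return float("nan")
    _, counts, n_ok = _per_day(series, cfg)
    eligible = counts >= cfg.min_readings_per_day
    if not eligible.any():
        return float("nan")
    frac = n_ok[eligible] / counts[eligible]
    meets = frac + _FRAC_EPS >= cfg.day_fraction
    return float(100.0 * meets.mean())


def _qualifying_pairs(series: TemperatureSeries, cfg: MetricConfig):
    """Boolean mask over consecutive-reading pairs: exactly one cadence apart
    (±1 min) with both readings at or above the threshold."""
    t = series.timestamps.astype("int64")
    dt = np.diff(t)
    cadence_s = cfg.cadence_minutes * 60
    valid = np.abs(dt - cadence_s) <= 60
    ok = series.temps >= cfg.threshold_c
    return valid & ok[:-1] & ok[1:]


def _included_days(series: TemperatureSeries, cfg: MetricConfig) -> np.ndarray:
    """Day set entering the hour metrics: eligible days, minus the terminal
    day of each month block under the default policy."""
    uniq, counts, _ = _per_day(series, cfg)
    days = uniq[counts >= cfg.min_readings_per_day]
    if len(days) and cfg.terminal_day_policy == "exclude_day":
        month = days.astype("datetime64[M]")
        last_of_block = np.r_[month[:-1] != month[1:], True]
        days = days[~last_of_block]
    return days


def _mean_hours_over_days(
    pair_days: np.ndarray, included: np.ndarray, cfg: MetricConfig
) -> float:
    """Average (qualifying segments × cadence/60) over the included days."""
    if len(included) == 0:
        return float("nan")
    idx = np.searchsorted(included, pair_days)
    idx_ok = (idx < len(included)) & (included[np.minimum(idx, len(included) - 1)] == pair_days)
    per_day = np.bincount(idx[idx_ok], minlength=len(included))
    return float(per_day.mean() * cfg.cadence_minutes / 60.0)


def mean_hours_per_day(
    series: TemperatureSeries, cfg: MetricConfig = MetricConfig()
) -> float:
    """Mean hours per day at or above the threshold, by 20-min segments.

    Hours on a day = qualifying segments attributed to that day (by the
    segment's first reading) × cadence/60; at most 24 with full coverage.
    NaN when no day is included.
    """
    if len(series) < 2:
        return float("nan")
    qual = _qualifying_pairs(series, cfg)
    pair_days = series.timestamps[:-1].astype("datetime64[D]")[qual]
    return _mean_hours_over_days(pair_days, _included_days(series, cfg), cfg)


def mean_night_hours(
    series: TemperatureSeries, cfg: MetricConfig = MetricConfig()
) -> float:
    """Mean hours per night (20:00–08:00 window) at or above the threshold.

    Night *n* spans ``night_start`` on day *n* to ``night_end`` on day
    *n*+1; a segment counts toward night *n* when it lies entirely inside
    the window. At most 12 hours per night at the defaults. Intended for the
    bedroom series. NaN when no night is included.
    """
    if len(series) < 2:
        return float("nan")
    start_s = cfg.night_start.hour * 3600 + cfg.night_start.minute * 60
    end_s = cfg.night_end.hour * 3600 + cfg.night_end.minute * 60
    if start_s <= end_s:
        raise ValueError("night window must cross midnight (night_start > night_end)")

    qual = _qualifying_pairs(series, cfg)
    t0 = series.timestamps[:-1][qual]
    t1 = series.timestamps[1:][qual]
    d0 = t0.astype("datetime64[D]")
    tod0 = (t0 - d0).astype("int64")
    tod1 = (t1 - t1.astype("datetime64[D]")).astype("int64")

    evening = tod0 >= start_s                 # before midnight: night = same date
    morning = tod1 <= end_s                   # after midnight: night = previous date
    # tod1 == 0 is the next-midnight reading, part of the previous night
    in_window = evening | morning
    night = np.where(evening, d0, d0 - np.timedelta64(1, "D"))[in_window]
    return _mean_hours_over_days(night, _included_days(series, cfg), cfg)


def compute_dwelling_metrics(
    series: Iterable[TemperatureSeries], cfg: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """Assemble the four outcome variables into one row per dwelling.

    Columns: ``mean_<room>``, ``pct_days_<room>``, ``hours_<room>`` for each
    monitored room, ``night_hours_bedroom``, and ``n_days_monitored`` (the
    maximum eligible-day count across rooms). Missing rooms yield NaN.
    """
    rows: dict[str, dict[str, float]] = {}
    for s in series:
        rec = rows.setdefault(s.dwelling_id, {})
        rec[f"mean_{s.room}"] = mean_winter_temperature(s)
        rec[f"pct_days_{s.room}"] = pct_days_meeting(s, cfg)
        rec[f"hours_{s.room}"] = mean_hours_per_day(s, cfg)
        if s.room == "bedroom":
            rec["night_hours_bedroom"] = mean_night_hours(s, cfg)
        rec["n_days_monitored"] = max(
            rec.get("n_days_monitored", 0), n_days_monitored(s, cfg)
        )
    cols = (
        [f"{kind}_{room}" for kind in ("mean", "pct_days", "hours") for room in ROOMS]
        + ["night_hours_bedroom", "n_days_monitored"]
    )
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    df.index.name = "dwelling_id"
    return df.sort_index()


def share_meeting_at_night(
    metrics: pd.DataFrame, min_hours: float = 9.0
) -> dict[str, float]:
    """Count and share of dwellings meeting the night recommendation.

    A dwelling meets it when its mean night hours at or above the threshold
    are at least ``min_hours`` (inclusive). Also reports dwellings with
    under one hour. Percentages are over dwellings with a computed night
    metric.
    """
    hours = metrics["night_hours_bedroom"].dropna()
    n = len(hours)
    count = int((hours >= min_hours).sum())
    below_1h = int((hours < 1.0).sum())
    return {
        "n": n,
        "count_meeting": count,
        "pct_meeting": 100.0 * count / n if n else float("nan"),
        "count_below_1h": below_1h,
        "pct_below_1h": 100.0 * below_1h / n if n else float("nan"),
    }
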