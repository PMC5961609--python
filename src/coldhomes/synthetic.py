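"""Synthetic logger panels with the structure of the EFUS 2011 winter sample.

The generator emulates the features of the private logger data that the
downstream analysis relies on: ~635 dwellings monitored in three rooms
(bedroom, living room, hallway) at 20-minute cadence over the three winter
months February 2011, December 2011 and January 2012; a wide between-home
spread of mean temperatures (SD ≈ 2.5 °C); diurnal heating patterns;
occasional low-temperature excursions when the home is empty; whole missing
days; sensor quantisation at 0.01 °C; and configurable additive shifts of
the home baseline for the long-term-disability (LTD) and over-64 groups.

The model per reading is::

    T(d, r, t) = B(d) + offset(r) + H(r, clock(t)) + eps
    B(d) = Normal(base_mean, between_home_sd) + ltd_effect·LTD(d) + age_effect·OVER64(d)

where ``H`` is a mean-centred heating-schedule component (so the winter mean
of a home is ``B(d) + offset(r)`` in expectation), ``eps`` is iid Gaussian
reading noise, absence episodes subtract a fixed drop over a contiguous
block of readings in all rooms, and values are quantised to the sensor
resolution. Identical (config, seed) yields bit-identical output.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from coldhomes import datasets
from coldhomes.io import ROOMS, TemperatureSeries

__all__ = ["SimConfig", "generate_households", "generate_series", "simulate_winter_means"]

_DEFAULT_MONTHS = ((2011, 2), (2011, 12), (2012, 1))
# Morning and evening heating windows (decimal hours), same in all rooms.
_DEFAULT_SCHEDULE = {room: ((6.5, 9.0), (16.0, 22.5)) for room in ROOMS}
# Living room warmest, matching the observed ordering of room means.
_DEFAULT_OFFSETS = {"bedroom": 0.0, "living_room": 0.7, "hallway": 0.0}


class ConfigurationError(ValueError):
    """A SimConfig field is outside its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic winter logger panel."""

    n_dwellings: int = 635
    months: tuple[tuple[int, int], ...] = _DEFAULT_MONTHS
    cadence_minutes: int = 20
    base_mean_c: float = 18.5
    between_home_sd_c: float = 2.5
    diurnal_amplitude_c: float = 1.5
    heating_schedule: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_SCHEDULE)
    )
    room_offsets_c: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS)
    )
    noise_sd_c: float = 0.8
    day_sd_c: float = 1.2              # day-to-day (weather-driven) baseline SD
    ltd_prevalence: float = datasets.N_LTD / datasets.N_DWELLINGS
    over64_prevalence: float = datasets.N_OVER64 / datasets.N_DWELLINGS
    ltd_effect_c: float = 0.5
    age_effect_c: float = 0.5
    absence_rate: float = 0.3          # expected absence episodes per dwelling-month
    absence_drop_c: float = 6.0
    absence_duration_days: tuple[float, float] = (1.0, 3.0)
    missing_day_rate: float = 0.03     # probability a dwelling×room day is lost
    sensor_resolution_c: float = 0.01
    include_categories: bool = True    # sample region/dwelling_type/tenure
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ltd_prevalence", "over64_prevalence", "missing_day_rate", "absence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        for name in ("between_home_sd_c", "noise_sd_c", "diurnal_amplitude_c", "day_sd_c"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_dwellings < 1:
            raise ConfigurationError("n_dwellings must be >= 1")
        if not self.months:
            raise ConfigurationError("months must be non-empty")
        if self.cadence_minutes <= 0 or 1440 % self.cadence_minutes != 0:
            raise ConfigurationError("cadence_minutes must divide 1440")
        if self.sensor_resolution_c <= 0:
            raise ConfigurationError("sensor_resolution_c must be > 0")
        lo, hi = self.absence_duration_days
        if not 0 < lo <= hi:
            raise ConfigurationError("absence_duration_days must satisfy 0 < lo <= hi")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _category_probs(counts: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    levels = list(counts)
    p = np.array([counts[k] for k in levels], dtype=float)
    return levels, p / p.sum()


def generate_households(config: SimConfig) -> pd.DataFrame:
    """Draw the household covariate table.

    LTD and over-64 indicators are independent Bernoulli draws at the
    configured prevalences; dwelling IDs are stable zero-padded strings.
    When ``include_categories`` is set, region, dwelling type and tenure are
    sampled from the published EFUS sample composition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_dwellings
    width = max(4, len(str(n)))
    df = pd.DataFrame(
        {
            "dwelling_id": [f"D{i + 1:0{width}d}" for i in range(n)],
            "ltd": rng.random(n) < config.ltd_prevalence,
            "over64": rng.random(n) < config.over64_prevalence,
        }
    )
    if config.include_categories:
        for col, counts in (
            ("region", datasets.REGION_COUNTS),
            ("dwelling_type", datasets.DWELLING_TYPE_COUNTS),
            ("tenure", datasets.TENURE_COUNTS),
        ):
            levels, p = _category_probs(counts)
            df[col] = rng.choice(levels, size=n, p=p)
    return df


def month_time_grid(
    months: Sequence[tuple[int, int]], cadence_minutes: int
) -> np.ndarray:
    """All reading timestamps (datetime64[s]) for the given months, time-sorted."""
    per_day = 1440 // cadence_minutes
    starts = []
    for year, month in sorted(months):
        n_days = calendar.monthrange(year, month)[1]
        first = np.datetime64(f"{year:04d}-{month:02d}-01", "s")
        days = first + np.arange(n_days) * np.timedelta64(86400, "s")
        starts.append(days)
    days = np.concatenate(starts)
    offsets = np.arange(per_day) * np.timedelta64(cadence_minutes * 60, "s")
    return (days[:, None] + offsets[None, :]).ravel()


def _heating_component(
    windows: Sequence[tuple[float, float]], amplitude: float, cadence_minutes: int
) -> np.ndarray:
    """Mean-centred within-day heating profile, one value per daily slot."""
    per_day = 1440 // cadence_minutes
    hours = np.arange(per_day) * cadence_minutes / 60.0
    on = np.zeros(per_day, dtype=bool)
    for start, end in windows:
        on |= (hours >= start) & (hours < end)
    if amplitude == 0.0:
        return np.zeros(per_day)
    return amplitude * (on.astype(float) - on.mean())


def generate_series(
    households: pd.DataFrame, config: SimConfig
) -> list[TemperatureSeries]:
    """Simulate the logger panel for every dwelling × room.

    Returns one :class:`TemperatureSeries` per dwelling × room, ordered by
    dwelling then room. Missing days are removed entirely; absence episodes
    subtract ``absence_drop_c`` across all rooms over a contiguous block.
    """
    if households.empty:
        raise ConfigurationError("households table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    times = month_time_grid(config.months, config.cadence_minutes)
    per_day = 1440 // config.cadence_minutes
    n_days = len(times) // per_day
    day_index = np.repeat(np.arange(n_days), per_day)
    t_seconds = times.astype("int64")

    # Per-month reading index ranges, for absence-episode placement.
    month_bounds = []
    pos = 0
    for year, month in sorted(config.months):
        n = calendar.monthrange(year, month)[1] * per_day
        month_bounds.append((pos, pos + n))
        pos += n

    heat = {
        room: np.tile(
            _heating_component(
                config.heating_schedule.get(room, ()),
                config.diurnal_amplitude_c,
                config.cadence_minutes,
            ),
            n_days,
        )
        for room in ROOMS
    }

    out: list[TemperatureSeries] = []
    episode_seconds = np.timedelta64(1, "D") / np.timedelta64(1, "s")
    for rec in households.itertuples(index=False):
        baseline = config.base_mean_c + config.between_home_sd_c * rng.standard_normal()
        baseline += config.ltd_effect_c * bool(rec.ltd)
        baseline += config.age_effect_c * bool(rec.over64)

        # Day-to-day (weather-driven) shift, shared across the dwelling's rooms.
        day_shift = np.repeat(
            rng.normal(0.0, config.day_sd_c, size=n_days), per_day
        )

        # Dwelling-level absence: the whole home cools while unoccupied.
        absent = np.zeros(len(times), dtype=bool)
        for lo, hi in month_bounds:
            for _ in range(rng.poisson(config.absence_rate)):
                start = rng.uniform(t_seconds[lo], t_seconds[hi - 1])
                dur = rng.uniform(*config.absence_duration_days) * episode_seconds
                absent |= (t_seconds >= start) & (t_seconds < start + dur)

        for room in ROOMS:
            missing_days = rng.random(n_days) < config.missing_day_rate
            noise = rng.normal(0.0, config.noise_sd_c, size=len(times))
            temps = (
                baseline
                + config.room_offsets_c.get(room, 0.0)
                + day_shift
                + heat[room]
                + noise
                - config.absence_drop_c * absent
            )
            res = config.sensor_resolution_c
            temps = np.round(temps / res) * res
            keep = ~missing_days[day_index]
            out.append(
                TemperatureSeries(
                    dwelling_id=str(rec.dwelling_id),
                    room=room,
                    timestamps=times[keep],
                    temps=temps[keep],
                )
            )
    return out


def simulate_winter_means(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-dwelling winter mean temperatures directly.

    Marginalises the reading-level model over time: the winter mean of a
    home is its baseline plus group effects, plus the (tiny) average of the
    reading noise. Used for Monte-Carlo studies of the group-comparison
    statistics where simulating full 20-minute panels would add nothing —
    the centred heating component and room offsets average out of the
    dwelling-level mean across rooms up to a constant.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    households = pd.DataFrame(
        {
            "dwelling_id": [f"D{i + 1:04d}" for i in range(config.n_dwellings)],
            "ltd": rng.random(config.n_dwellings) < config.ltd_prevalence,
            "over64": rng.random(config.n_dwellings) < config.over64_prevalence,
        }
    )
    grid = month_time_grid(config.months, config.cadence_minutes)
    n_readings = len(grid) * len(ROOMS)
    n_days = len(grid) // (1440 // config.cadence_minutes)
    # reading noise and day-to-day shifts average down in the winter mean
    sd_noise_mean = np.sqrt(
        config.noise_sd_c**2 / max(n_readings, 1) + config.day_sd_c**2 / max(n_days, 1)
    )
    means = (
        config.base_mean_c
        + config.between_home_sd_c * rng.standard_normal(config.n_dwellings)
        + config.ltd_effect_c * households["ltd"].to_numpy()
        + config.age_effect_c * households["over64"].to_numpy()
        + sd_noise_mean * rng.standard_normal(config.n_dwellings)
    )
    return households, means
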