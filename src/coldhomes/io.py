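"""Reading and writing logger panels and household covariate tables.

Two CSV dialects are defined:

* logger CSV — header ``dwelling_id,room,timestamp,temp_c``; one row per
  reading, timestamps ISO-8601 local naive (the winter analysis window has
  no DST transitions), temperatures in °C at 0.01 °C resolution.
* covariates CSV — header ``dwelling_id,ltd,over64[,region,dwelling_type,tenure]``;
  one row per dwelling, booleans accepted as 0/1, true/false, yes/no
  (case-insensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOMS = ("bedroom", "living_room", "hallway")

#: Plausibility bounds for indoor readings, °C. Rows outside are rejected on read.
TEMP_BOUNDS_C = (-20.0, 50.0)

_BOOL_TOKENS = {
    "0": False, "1": True,
    "false": False, "true": True,
    "no": False, "yes": True,
}


class ValidationError(ValueError):
    """A file violated the schema; ``rows`` lists offending row indices."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class TemperatureSeries:
    """Ordered readings for one dwelling × room at nominal 20-min cadence.

    Timestamps are naive local datetimes, strictly increasing; gaps are
    allowed and denote missing data.
    """

    dwelling_id: str
    room: str
    timestamps: np.ndarray = field(repr=False)  # datetime64[s], sorted strictly
    temps: np.ndarray = field(repr=False)       # float64, °C

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.timestamps.shape != self.temps.shape:
            raise ValueError("timestamps and temps must have equal length")
        if self.room not in ROOMS:
            raise ValueError(f"unknown room {self.room!r}; expected one of {ROOMS}")
        if len(self.timestamps) > 1 and not (np.diff(self.timestamps) > np.timedelta64(0, "s")).all():
            raise ValueError(
                f"timestamps not strictly increasing for {self.dwelling_id}/{self.room}"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dwelling_id": self.dwelling_id,
                "room": self.room,
                "timestamp": self.timestamps,
                "temp_c": self.temps,
            }
        )


def series_to_frame(series: Iterable[TemperatureSeries]) -> pd.DataFrame:
    """Concatenate series into one long DataFrame (empty frame if no series)."""
    frames = [s.to_frame() for s in series]
    if not frames:
        return pd.DataFrame(columns=["dwelling_id", "room", "timestamp", "temp_c"])
    return pd.concat(frames, ignore_index=True)


def frame_to_series(df: pd.DataFrame) -> list[TemperatureSeries]:
    """Split a long frame into per dwelling × room series, time-sorted."""
    out: list[TemperatureSeries] = []
    for (dw, room), grp in df.groupby(["dwelling_id", "room"], sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            TemperatureSeries(
                dwelling_id=str(dw),
                room=str(room),
                timestamps=grp["timestamp"].to_numpy(dtype="datetime64[s]"),
                temps=grp["temp_c"].to_numpy(dtype=float),
            )
        )
    return out


def read_logger_csv(
    path: str | Path,
    bounds: tuple[float, float] = TEMP_BOUNDS_C,
) -> tuple[list[TemperatureSeries], int]:
    """Read a logger CSV into per dwelling × room series.

    Rows with temperatures outside the plausibility ``bounds`` are dropped
    and counted (returned as the second element, also logged). Unknown room
    labels, unparsable timestamps and duplicate (dwelling, room, timestamp)
    rows raise :class:`ValidationError` listing offending row indices
    (0-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"dwelling_id": str, "room": str})
    required = {"dwelling_id", "room", "timestamp", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"logger CSV missing columns: {sorted(missing)}")

    bad_room = ~df["room"].isin(ROOMS)
    if bad_room.any():
        rows = df.index[bad_room].tolist()
        raise ValidationError(
            f"unknown room labels {sorted(df.loc[bad_room, 'room'].unique())} "
            f"at rows {rows[:10]}",
            rows,
        )

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad_ts = ts.isna()
    if bad_ts.any():
        rows = df.index[bad_ts].tolist()
        raise ValidationError(f"unparsable timestamps at rows {rows[:10]}", rows)
    df = df.assign(timestamp=ts)

    dup = df.duplicated(subset=["dwelling_id", "room", "timestamp"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValidationError(
            f"duplicate (dwelling, room, timestamp) rows at {rows[:10]}", rows
        )

    temp = pd.to_numeric(df["temp_c"], errors="coerce")
    implausible = ~np.isfinite(temp) | (temp < bounds[0]) | (temp > bounds[1])
    n_rejected = int(implausible.sum())
    if n_rejected:
        logger.warning("rejected %d implausible reading(s) outside %s °C", n_rejected, bounds)
        df = df.loc[~implausible.to_numpy()]
    df = df.assign(temp_c=temp.loc[df.index])

    return frame_to_series(df), n_rejected


def write_logger_csv(series: Iterable[TemperatureSeries], path: str | Path) -> None:
    """Write series to the logger CSV dialect (temperatures at 2 decimals)."""
    df = series_to_frame(series)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["temp_c"] = df["temp_c"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    tokens = col.astype(str).str.strip().str.lower()
    bad = ~tokens.isin(_BOOL_TOKENS)
    if bad.any():
        rows = col.index[bad].tolist()
        raise ValidationError(
            f"column {name!r}: unrecognised boolean values "
            f"{sorted(tokens[bad].unique())} at rows {rows[:10]}",
            rows,
        )
    return tokens.map(_BOOL_TOKENS).astype(bool)


def read_households_csv(path: str | Path) -> pd.DataFrame:
    """Read a covariates CSV into a DataFrame of household records.

    Returns columns ``dwelling_id`` (str), ``ltd`` and ``over64`` (bool) and
    any of the optional category columns present (``region``,
    ``dwelling_type``, ``tenure``). Dwelling IDs must be unique.
    """
    df = pd.read_csv(path, dtype={"dwelling_id": str})
    required = {"dwelling_id", "ltd", "over64"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"covariates CSV missing columns: {sorted(missing)}")
    dup = df["dwelling_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate dwelling_id values: {sorted(df.loc[dup, 'dwelling_id'].unique())[:10]}",
            df.index[dup].tolist(),
        )
    df = df.copy()
    df["ltd"] = _parse_bool(df["ltd"], "ltd")
    df["over64"] = _parse_bool(df["over64"], "over64")
    keep = ["dwelling_id", "ltd", "over64"] + [
        c for c in ("region", "dwelling_type", "tenure") if c in df.columns
    ]
    return df[keep]


def write_households_csv(households: pd.DataFrame, path: str | Path) -> None:
    df = households.copy()
    for col in ("ltd", "over64"):
        df[col] = df[col].astype(bool).map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def check_linkage(
    series: Iterable[TemperatureSeries], households: pd.DataFrame
) -> None:
    """Raise if any logged dwelling lacks a covariate record (lists the IDs)."""
    logged = {s.dwelling_id for s in series}
    known = set(households["dwelling_id"].astype(str))
    orphans = sorted(logged - known)
    if orphans:
        raise ValidationError(
            f"{len(orphans)} dwelling(s) have logger data but no covariate record: "
            f"{orphans[:20]}"
        )
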