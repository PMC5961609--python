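"""Winter-window selection and low-extreme (absence) correction.

Extremely low readings typically reflect an empty home rather than the
occupied thermal state, so readings more than ``multiplier`` interquartile
ranges below the first quartile — the Tukey lower fence — are removed.
The fence is computed once per dwelling × room on the combined readings of
all window months, and only the low side is screened: cold excursions, not
warm ones, are the absence signature.

Re-running the correction on already-cleaned data recomputes the quartiles
on the reduced sample and may remove further points; the operation is not
idempotent and is intended to be applied exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from coldhomes.io import TemperatureSeries

__all__ = ["FenceConfig", "select_window", "remove_low_extremes", "preprocess_panel"]


@dataclass(frozen=True)
class FenceConfig:
    """Tukey lower-fence parameters: fence = Q1 − multiplier × IQR."""

    multiplier: float = 1.5
    #: Quartile convention; "linear" is NumPy's interpolation between order
    #: statistics (classical type 7). Any np.quantile method name is accepted.
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("fence multiplier must be > 0")


def select_window(
    series: TemperatureSeries, months: Sequence[tuple[int, int]]
) -> TemperatureSeries:
    """Keep only readings whose calendar date falls in the listed (year, month) pairs."""
    if not months:
        raise ValueError("months must be non-empty")
    if len(series) == 0:
        return series
    # encode (year, month) as year*100 + month for a vectorised membership test
    months_abs = series.timestamps.astype("datetime64[M]").astype(int)
    ym_code = (months_abs // 12 + 1970) * 100 + (months_abs % 12 + 1)
    wanted = np.array([int(y) * 100 + int(m) for y, m in months])
    keep = np.isin(ym_code, wanted)
    return TemperatureSeries(
        series.dwelling_id, series.room, series.timestamps[keep], series.temps[keep]
    )


def lower_fence(temps: np.ndarray, fence: FenceConfig = FenceConfig()) -> float:
    """Q1 − multiplier × IQR of the given readings."""
    q1, q3 = np.quantile(temps, [0.25, 0.75], method=fence.quantile_method)
    return float(q1 - fence.multiplier * (q3 - q1))


def remove_low_extremes(
    series: TemperatureSeries,
    fence: FenceConfig = FenceConfig(),
    threshold: float | None = None,
) -> tuple[TemperatureSeries, int]:
    """Drop readings strictly below the Tukey lower fence.

    The fence is computed on this series' own readings unless an explicit
    ``threshold`` is passed (used for pooled per-dwelling fences). Series
    with fewer than four readings pass through unchanged with a warning, as
    quartiles are not meaningfully defined.
    """
    if threshold is None:
        if len(series) < 4:
            warnings.warn(
                f"{series.dwelling_id}/{series.room}: {len(series)} reading(s) "
                "< 4; low-extreme correction skipped",
                stacklevel=2,
            )
            return series, 0
        threshold = lower_fence(series.temps, fence)
    keep = ~(series.temps < threshold)  # strictly-below readings removed
    removed = int((~keep).sum())
    cleaned = TemperatureSeries(
        series.dwelling_id, series.room, series.timestamps[keep], series.temps[keep]
    )
    return cleaned, removed


def preprocess_panel(
    series: Iterable[TemperatureSeries],
    months: Sequence[tuple[int, int]],
    fence: FenceConfig = FenceConfig(),
    pool_rooms: bool = False,
) -> tuple[list[TemperatureSeries], pd.DataFrame]:
    """Window-select and fence-correct a whole panel.

    By default the fence is computed per dwelling × room; with
    ``pool_rooms`` a single per-dwelling fence is computed on the pooled
    readings of all rooms and applied to each. Dwellings × rooms left empty
    by the window are dropped and flagged in the report.

    Returns the cleaned series plus a report frame with one row per input
    series: ``dwelling_id, room, n_readings, n_removed, empty_window``.
    """
    windowed = [select_window(s, months) for s in series]

    pooled_fence: dict[str, float] = {}
    if pool_rooms:
        by_dwelling: dict[str, list[np.ndarray]] = {}
        for s in windowed:
            by_dwelling.setdefault(s.dwelling_id, []).append(s.temps)
        for dw, chunks in by_dwelling.items():
            temps = np.concatenate(chunks)
            if len(temps) >= 4:
                pooled_fence[dw] = lower_fence(temps, fence)

    cleaned: list[TemperatureSeries] = []
    rows = []
    for s in windowed:
        if len(s) == 0:
            rows.append((s.dwelling_id, s.room, 0, 0, True))
            continue
        thr = pooled_fence.get(s.dwelling_id) if pool_rooms else None
        out, removed = remove_low_extremes(s, fence, threshold=thr)
        cleaned.append(out)
        rows.append((s.dwelling_id, s.room, len(out), removed, False))
    report = pd.DataFrame(
        rows, columns=["dwelling_id", "room", "n_readings", "n_removed", "empty_window"]
    )
    return cleaned, report
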