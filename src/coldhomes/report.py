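"""Study-style summary outputs.

Assembles the descriptive tables and headline numbers a cold-homes exposure
study reports: sample composition by region / dwelling type / tenure,
per-room metric summaries, group-wise medians of daily hours at the
criterion (rendered HH:MM), the night-criterion shares, and kernel-density
curves for the per-dwelling metric distributions. JSON is the canonical
output; CSV renderers sit on top. Regeneration from identical inputs is
byte-identical (stable ordering, fixed float formatting).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from coldhomes.io import ROOMS
from coldhomes.metrics import share_meeting_at_night
from coldhomes.stats import StatResult, kde_pdf

logger = logging.getLogger(__name__)

__all__ = [
    "composition_table",
    "hours_to_hhmm",
    "hours_by_group_table",
    "metric_summary_table",
    "headline_summary",
    "density_curves",
    "write_report",
]

CATEGORY_COLUMNS = ("region", "dwelling_type", "tenure")


def composition_table(
    households: pd.DataFrame, columns: Iterable[str] = CATEGORY_COLUMNS
) -> pd.DataFrame:
    """Counts and percentages per category level, one block per column.

    Percentages are over the dwellings in the block and formatted to two
    decimals; within each block they sum to 100 up to rounding. Category
    columns absent from the table are omitted with a log note.
    """
    blocks = []
    for col in columns:
        if col not in households.columns:
            logger.info("composition: column %r absent, block omitted", col)
            continue
        counts = households[col].value_counts()
        counts = counts.loc[sorted(counts.index)]
        total = int(counts.sum())
        for level, n in counts.items():
            blocks.append(
                {
                    "block": col,
                    "level": level,
                    "n": int(n),
                    "pct": round(100.0 * n / total, 2),
                }
            )
    return pd.DataFrame(blocks, columns=["block", "level", "n", "pct"])


def hours_to_hhmm(hours: float) -> str:
    """Render decimal hours as ``HH:MM``, minutes rounded; NaN → ``"na"``."""
    if hours is None or (isinstance(hours, float) and math.isnan(hours)):
        return "na"
    minutes = int(round(hours * 60))
    return f"{minutes // 60}:{minutes % 60:02d}"


def hours_by_group_table(
    metrics: pd.DataFrame, households: pd.DataFrame
) -> pd.DataFrame:
    """Median daily hours at the criterion per room, split by LTD and age group.

    Medians are computed on decimal hours and then rendered HH:MM. Empty
    groups render as ``"na"``.
    """
    hh = households.set_index("dwelling_id")
    joined = metrics.join(hh[["ltd", "over64"]], how="inner")
    groups = {
        "no_ltd": ~joined["ltd"],
        "ltd": joined["ltd"],
        "below_65": ~joined["over64"],
        "above_64": joined["over64"],
    }
    rows = {}
    for room in ROOMS:
        col = f"hours_{room}"
        rows[room] = {
            name: hours_to_hhmm(float(joined.loc[mask, col].median()))
            if mask.any()
            else "na"
            for name, mask in groups.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "room"
    return out


def metric_summary_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and median of each per-room metric across dwellings."""
    rows = []
    for kind in ("mean", "pct_days", "hours"):
        for room in ROOMS:
            col = f"{kind}_{room}"
            vals = metrics[col].dropna()
            rows.append(
                {
                    "metric": kind,
                    "room": room,
                    "mean": round(float(vals.mean()), 2),
                    "sd": round(float(vals.std(ddof=1)), 2),
                    "median": round(float(vals.median()), 2),
                    "n": int(len(vals)),
                }
            )
    vals = metrics["night_hours_bedroom"].dropna()
    rows.append(
        {
            "metric": "night_hours",
            "room": "bedroom",
            "mean": round(float(vals.mean()), 2),
            "sd": round(float(vals.std(ddof=1)), 2),
            "median": round(float(vals.median()), 2),
            "n": int(len(vals)),
        }
    )
    return pd.DataFrame(rows)


def headline_summary(
    metrics: pd.DataFrame,
    households: pd.DataFrame,
    stat_results: Mapping[str, Iterable[StatResult]] | None = None,
    alpha: float = 0.05,
    night_min_hours: float = 9.0,
) -> dict:
    """Machine-readable headline numbers for a pipeline run.

    Per-room medians of each metric, the night-criterion shares, LTD and
    age-group sizes, and (if statistical results are supplied, keyed by
    outcome name) the list of effects significant at ``alpha``.
    """
    summary: dict = {
        "n_dwellings": int(len(metrics)),
        "n_ltd": int(households["ltd"].sum()),
        "n_over64": int(households["over64"].sum()),
        "median_mean_temp_c": {
            room: round(float(metrics[f"mean_{room}"].median()), 2) for room in ROOMS
        },
        "median_pct_days_meeting": {
            room: round(float(metrics[f"pct_days_{room}"].median()), 1) for room in ROOMS
        },
        "median_hours_per_day": {
            room: hours_to_hhmm(float(metrics[f"hours_{room}"].median()))
            for room in ROOMS
        },
        "median_night_hours": hours_to_hhmm(
            float(metrics["night_hours_bedroom"].median())
        ),
        "night_criterion": share_meeting_at_night(metrics, min_hours=night_min_hours),
        "significant_effects": [],
    }
    if stat_results:
        for outcome, results in sorted(stat_results.items()):
            for r in results:
                if r.p < alpha:
                    summary["significant_effects"].append(
                        {
                            "outcome": outcome,
                            "effect": r.effect,
                            "F": round(r.F, 2),
                            "df": [r.df_num, r.df_den],
                            "p": round(r.p, 4),
                        }
                    )
    return summary


def density_curves(
    metrics: pd.DataFrame, columns: Iterable[str], n_grid: int = 256
) -> pd.DataFrame:
    """Kernel-density curve data for the requested metric columns.

    Long frame with columns ``metric, x, density``; metrics with fewer than
    two distinct values are skipped with a log note.
    """
    frames = []
    for col in columns:
        vals = metrics[col].dropna().to_numpy()
        try:
            grid, dens = kde_pdf(vals, n_grid=n_grid)
        except ValueError as exc:
            logger.info("density: %s skipped (%s)", col, exc)
            continue
        frames.append(pd.DataFrame({"metric": col, "x": grid, "density": dens}))
    if not frames:
        return pd.DataFrame(columns=["metric", "x", "density"])
    return pd.concat(frames, ignore_index=True)


def write_report(
    out_dir: str | Path,
    metrics: pd.DataFrame,
    households: pd.DataFrame,
    stat_results: Mapping[str, Iterable[StatResult]] | None = None,
) -> Path:
    """Write the full report bundle (JSON + CSV tables) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    composition_table(households).to_csv(out / "composition.csv", index=False)
    metric_summary_table(metrics).to_csv(out / "metric_summary.csv", index=False)
    hours_by_group_table(metrics, households).to_csv(out / "hours_by_group.csv")
    curves = density_curves(
        metrics, [f"mean_{room}" for room in ROOMS] + ["night_hours_bedroom"]
    )
    curves.to_csv(out / "density_curves.csv", index=False, float_format="%.6f")
    summary = headline_summary(metrics, households, stat_results)
    if stat_results:
        summary["all_effects"] = {
            outcome: [r.to_dict() for r in results]
            for outcome, results in sorted(stat_results.items())
        }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
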