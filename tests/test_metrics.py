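import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldhomes.io import TemperatureSeries
from coldhomes.metrics import (
    MetricConfig,
    compute_dwelling_metrics,
    day_fraction_at_threshold,
    mean_hours_per_day,
    mean_night_hours,
    mean_winter_temperature,
    pct_days_meeting,
    share_meeting_at_night,
)

from conftest import make_series

CFG = MetricConfig()


def multi_day_series(day_temps, start_date="2011-02-01", extra_midnight=True):
    """Series of full 72-reading days; ``day_temps`` is one scalar or vector
    per day. With ``extra_midnight`` a final 00:00 reading closes the last
    cross-midnight segment."""
    temps = []
    for day in day_temps:
        day = np.asarray(day, dtype=float)
        temps.append(np.full(72, day) if day.ndim == 0 else day)
    temps = np.concatenate(temps)
    if extra_midnight:
        temps = np.r_[temps, temps[-1]]
    return make_series(temps, start=f"{start_date}T00:00:00")


def brute_force_hours(series: TemperatureSeries, cfg: MetricConfig):
    """Independent pairwise scan: hours at threshold per day and per night."""
    day_hours: dict = {}
    night_hours: dict = {}
    ts = series.timestamps.astype("datetime64[s]").astype("int64")
    for i in range(len(series) - 1):
        if abs((ts[i + 1] - ts[i]) - cfg.cadence_minutes * 60) > 60:
            continue
        if not (series.temps[i] >= cfg.threshold_c and series.temps[i + 1] >= cfg.threshold_c):
            continue
        t0, t1 = series.timestamps[i], series.timestamps[i + 1]
        day = t0.astype("datetime64[D]")
        day_hours[day] = day_hours.get(day, 0) + 1
        sec0 = int((t0 - day).astype("timedelta64[s]").astype(int))
        sec1 = int((t1 - t1.astype("datetime64[D]")).astype("timedelta64[s]").astype(int))
        start_s = cfg.night_start.hour * 3600
        end_s = cfg.night_end.hour * 3600
        if sec0 >= start_s:
            night_hours[day] = night_hours.get(day, 0) + 1
        elif sec1 <= end_s:
            prev = day - np.timedelta64(1, "D")
            night_hours[prev] = night_hours.get(prev, 0) + 1

    dates, counts = np.unique(series.timestamps.astype("datetime64[D]"), return_counts=True)
    days = [d for d, c in zip(dates, counts) if c >= cfg.min_readings_per_day]
    if cfg.terminal_day_policy == "exclude_day":
        months = {d.astype("datetime64[M]") for d in days}
        last = {max(d for d in days if d.astype("datetime64[M]") == m) for m in months}
        days = [d for d in days if d not in last]
    if not days:
        return float("nan"), float("nan")
    f = cfg.cadence_minutes / 60.0
    return (
        float(np.mean([day_hours.get(d, 0) * f for d in days])),
        float(np.mean([night_hours.get(d, 0) * f for d in days])),
    )


# ---------------------------------------------------------------- mean (a)


def test_mean_temperature_examples():
    assert mean_winter_temperature(make_series(np.full(10, 18.5))) == 18.5
    assert mean_winter_temperature(make_series([17.0, 19.0])) == 18.0


def test_mean_temperature_equals_naive_loop(small_panel):
    _, series = small_panel
    s = series[0]
    total = 0.0
    for v in s.temps:
        total += v
    assert mean_winter_temperature(s) == pytest.approx(total / len(s), rel=1e-12)


# ------------------------------------------------------ day criterion (b)


def test_day_fraction_boundary_68_of_72():
    day = np.r_[np.full(68, 18.0), np.full(4, 16.0)]
    frac = day_fraction_at_threshold(day)
    assert frac == pytest.approx(68 / 72)
    assert round(100 * frac, 1) == 94.4


def test_day_fraction_all_meeting_is_one():
    assert day_fraction_at_threshold(np.full(72, 18.0)) == 1.0


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(min_value=10, max_value=25, allow_nan=False), min_size=1, max_size=72))
def test_day_fraction_matches_brute_force(day):
    expected = sum(1 for v in day if v >= 18.0) / len(day)
    assert day_fraction_at_threshold(np.array(day)) == pytest.approx(expected)


def test_exactly_68_of_72_each_day_meets_inclusively():
    day = np.r_[np.full(68, 18.0), np.full(4, 16.0)]
    s = multi_day_series([day] * 5, extra_midnight=False)
    assert pct_days_meeting(s, CFG) == 100.0


def test_pct_days_with_planted_pattern():
    """30 of 90 full days meet the criterion → 33.3%."""
    days = [19.0] * 30 + [15.0] * 60
    s = multi_day_series(days, extra_midnight=False)
    assert pct_days_meeting(s, CFG) == pytest.approx(100 * 30 / 90)


def test_short_days_excluded_from_denominator():
    full = np.full(72, 19.0)
    s_full = multi_day_series([full, full], extra_midnight=False)
    # second day has only 10 readings: below min_readings_per_day
    short = make_series(np.full(10, 15.0), start="2011-02-02T00:00:00")
    combined = TemperatureSeries(
        "D0001",
        "bedroom",
        np.r_[s_full.timestamps[:72], short.timestamps],
        np.r_[s_full.temps[:72], short.temps],
    )
    assert pct_days_meeting(combined, CFG) == 100.0


# --------------------------------------------------------- hours (c), (d)


def test_constant_warm_day_with_next_midnight_gives_24h():
    s = multi_day_series([21.0, 21.0])  # 2 days + closing midnight reading
    cfg = CFG.with_(terminal_day_policy="keep_day")
    assert mean_hours_per_day(s, cfg) == 24.0


def test_constant_cold_day_gives_zero_hours():
    s = multi_day_series([15.0, 15.0])
    assert mean_hours_per_day(s, CFG.with_(terminal_day_policy="keep_day")) == 0.0


def test_alternating_readings_give_no_qualifying_segments():
    temps = np.tile([19.0, 17.0], 72)
    s = make_series(temps)
    assert mean_hours_per_day(s, CFG.with_(terminal_day_policy="keep_day")) == 0.0


def test_terminal_day_of_month_block_excluded_by_default():
    # 2 warm days + a cold terminal day: the terminal day is excluded.
    # Day 1 keeps its cross-midnight segment (72 segments = 24 h); day 2's
    # cross-midnight pair fails the threshold on the cold side (71 segments).
    s = multi_day_series([21.0, 21.0, 15.0], extra_midnight=False)
    hours = mean_hours_per_day(s, CFG)
    assert hours == pytest.approx((72 / 3 + 71 / 3) / 2)


def test_gap_breaks_segment():
    # one-hour gap in an otherwise warm day: the bridging pair is not a segment
    t0 = np.datetime64("2011-02-01T00:00:00", "s")
    ts = [t0 + i * np.timedelta64(1200, "s") for i in range(36)]
    ts += [t0 + np.timedelta64(3600 * 13 + 1200 * i, "s") for i in range(33)]
    s = TemperatureSeries("D1", "bedroom", np.array(ts), np.full(69, 21.0))
    cfg = CFG.with_(terminal_day_policy="keep_day")
    # 35 + 32 qualifying segments of 1/3 h
    assert mean_hours_per_day(s, cfg) == pytest.approx(67 / 3)


def test_night_constant_warm_gives_12h():
    # default policy: the terminal day (whose night has no next morning) is excluded
    s = multi_day_series([21.0, 21.0])
    assert mean_night_hours(s, CFG) == pytest.approx(12.0)


def test_night_threshold_boundary_inclusive():
    s = multi_day_series([18.0, 18.0])
    assert mean_night_hours(s, CFG) == pytest.approx(12.0)


def test_night_partial_window_hand_counted():
    """18 °C from 23:00 through 08:00, 17 °C otherwise → 27 segments = 9 h."""
    hours_grid = np.arange(72) / 3.0
    day = np.where((hours_grid >= 23.0) | (hours_grid <= 8.0), 18.0, 17.0)
    temps = np.r_[day, day, [18.0]]
    s = make_series(temps, start="2011-02-01T00:00:00")
    assert mean_night_hours(s, CFG) == pytest.approx(9.0)


def test_hours_match_brute_force_on_random_days():
    """Vectorised segment logic equals an independent pairwise scan."""
    rng = np.random.default_rng(314)
    for _ in range(20):
        n_days = rng.integers(2, 6)
        temps = rng.normal(18.0, 2.0, size=n_days * 72)
        s = make_series(temps, start="2011-02-01T00:00:00")
        # knock out random readings to create gaps
        keep = rng.random(len(temps)) > 0.05
        s = TemperatureSeries("D1", "bedroom", s.timestamps[keep], s.temps[keep])
        for policy in ("exclude_day", "keep_day"):
            cfg = CFG.with_(terminal_day_policy=policy)
            bf_day, bf_night = brute_force_hours(s, cfg)
            np.testing.assert_allclose(mean_hours_per_day(s, cfg), bf_day, equal_nan=True)
            np.testing.assert_allclose(mean_night_hours(s, cfg), bf_night, equal_nan=True)


# --------------------------------------------------- invariants & assembly


def test_bounds_and_threshold_monotonicity(small_panel):
    _, series = small_panel
    for s in series[:6]:
        for cfg in (CFG, CFG.with_(threshold_c=19.0)):
            h = mean_hours_per_day(s, cfg)
            nh = mean_night_hours(s, cfg)
            p = pct_days_meeting(s, cfg)
            assert 0.0 <= h <= 24.0
            assert 0.0 <= nh <= 12.0
            assert 0.0 <= p <= 100.0
        # raising the threshold never increases any metric
        assert mean_hours_per_day(s, CFG.with_(threshold_c=19.0)) <= mean_hours_per_day(s, CFG)
        assert mean_night_hours(s, CFG.with_(threshold_c=19.0)) <= mean_night_hours(s, CFG)
        assert pct_days_meeting(s, CFG.with_(threshold_c=19.0)) <= pct_days_meeting(s, CFG)
        # lowering the day fraction never decreases the share of meeting days
        assert pct_days_meeting(s, CFG.with_(day_fraction=0.5)) >= pct_days_meeting(s, CFG)


def test_everything_above_threshold_saturates_metrics():
    s = multi_day_series([21.0] * 4)
    assert pct_days_meeting(s, CFG) == 100.0
    assert mean_hours_per_day(s, CFG) == 24.0
    assert mean_night_hours(s, CFG) == 12.0


def test_compute_dwelling_metrics_table_shape(small_panel):
    _, series = small_panel
    table = compute_dwelling_metrics(series)
    assert table.index.name == "dwelling_id"
    assert len(table) == 8
    assert {"mean_bedroom", "pct_days_living_room", "hours_hallway",
            "night_hours_bedroom", "n_days_monitored"} <= set(table.columns)
    assert (table["n_days_monitored"] <= 28).all()


def test_share_meeting_at_night_counts():
    metrics = pd.DataFrame({"night_hours_bedroom": [12.0, 9.0, 8.9, 0.5, np.nan]})
    out = share_meeting_at_night(metrics)
    assert out["n"] == 4
    assert out["count_meeting"] == 2  # the 9.0 boundary is inclusive
    assert out["pct_meeting"] == pytest.approx(50.0)
    assert out["count_below_1h"] == 1
    assert out["pct_below_1h"] == pytest.approx(25.0)


def test_all_warm_panel_meets_night_criterion_everywhere():
    metrics = pd.DataFrame({"night_hours_bedroom": np.full(10, 12.0)})
    assert share_meeting_at_night(metrics)["pct_meeting"] == 100.0
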