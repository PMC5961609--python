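import numpy as np
import pytest

from coldhomes.io import TemperatureSeries
from coldhomes.synthetic import SimConfig, generate_households, generate_series

CADENCE_S = 20 * 60


def make_series(
    temps,
    start="2011-02-01T00:00:00",
    cadence_minutes=20,
    dwelling_id="D0001",
    room="bedroom",
) -> TemperatureSeries:
    """Series with regularly spaced readings starting at `start`."""
    temps = np.asarray(temps, dtype=float)
    t0 = np.datetime64(start, "s")
    ts = t0 + np.arange(len(temps)) * np.timedelta64(cadence_minutes * 60, "s")
    return TemperatureSeries(dwelling_id, room, ts, temps)


def day_of(temp, date, n=72):
    """One calendar day of constant readings (72 at 20-min cadence)."""
    return np.full(n, float(temp)), np.datetime64(f"{date}T00:00:00", "s")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_dwellings=8, months=((2011, 2),), seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    households = generate_households(small_config)
    series = generate_series(households, small_config)
    return households, series
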