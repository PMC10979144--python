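import numpy as np
import pandas as pd
import pytest

from pmhia.exposure import DailySeries
from pmhia.synthetic import SimConfig, simulate_hourly


def write_csv(path, rows):
    """Write (timestamp, value) rows as the two-column CSV dialect."""
    pd.DataFrame(rows, columns=["timestamp", "value"]).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic city, shared across tests."""
    return simulate_hourly(SimConfig(seed=1234))


@pytest.fixture(scope="session")
def sim_clean():
    """Noiseless, gapless, sentinel-free city: exact identifiability."""
    return simulate_hourly(
        SimConfig(seed=99, noise_sd=0.0, missing_prob=0.0, sentinel_prob=0.0)
    )


def daily_from_values(values, start="2019-01-01"):
    """Build a DailySeries from raw daily-mean values."""
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(dates, values, np.full(len(values), 24), "pm25")
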