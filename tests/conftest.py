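import numpy as np
import pandas as pd
import pytest

from cherrychill.thermal import HourlyTemperatureSeries


@pytest.fixture
def make_series():
    """Factory for an hourly series starting at a fixed autumn timestamp."""

    def _make(temps, start="2014-09-21 00:00"):
        temps = np.asarray(temps, dtype=float)
        times = pd.date_range(start, periods=len(temps), freq="h")
        return HourlyTemperatureSeries(times=times, temps=temps, season_start=start)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20140921)
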