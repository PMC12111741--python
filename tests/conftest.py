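import numpy as np
import pandas as pd
import pytest

from graintemp.synthetic_granary import TemperatureSeries


def series_from_values(values, cadence_hours=24.0, label="test"):
    values = np.asarray(values, dtype=float)
    idx = pd.date_range("2024-01-01", periods=len(values),
                        freq=pd.Timedelta(hours=cadence_hours))
    return TemperatureSeries(idx, values, cadence_hours, label=label)


@pytest.fixture
def make_series():
    return series_from_values


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
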