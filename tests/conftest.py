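import numpy as np
import pandas as pd
import pytest

from gddrn import SimulationConfig, WeatherSeries, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small study: 3 cycles x 20 lines, 6 environments, 300 SNPs."""
    return SimulationConfig(n_cycles=3, lines_per_cycle=20, n_snps=300)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config, seed=101)


@pytest.fixture(scope="session")
def tiny_design(tiny_dataset):
    return tiny_dataset.design()


def make_weather(env_id="env1", days=320, tavg=10.0, tmin=None, tmax=None,
                 precip=2.0, evap=1.0, glorad=5.0, vpd=0.3, year=2015):
    """Constant-valued weather series helper."""
    sowing = pd.Timestamp(year - 1, 10, 1)
    dates = pd.date_range(sowing, periods=days, freq="D")
    n = len(dates)

    def arr(v):
        return np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)

    tavg_a = arr(tavg)
    records = pd.DataFrame(
        {
            "tmin": arr(tmin) if tmin is not None else tavg_a - 2.0,
            "tavg": tavg_a,
            "tmax": arr(tmax) if tmax is not None else tavg_a + 2.0,
            "precip": arr(precip),
            "evap": arr(evap),
            "glorad": arr(glorad),
            "vpd": arr(vpd),
        },
        index=dates,
    )
    return WeatherSeries(env_id, records, sowing, dates[-1])
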