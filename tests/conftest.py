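import numpy as np
import pandas as pd
import pytest

import tidewave as tw

T0 = pd.Timestamp("2007-01-01")


def make_series(values, step=60.0, start=T0, variable="", units=""):
    return tw.TimeSeries(start, step, np.asarray(values, dtype=float), variable, units)


@pytest.fixture(scope="session")
def m2_s2_tide_180d():
    """Noise-free two-constituent water level, 180 days at 10-min cadence."""
    cfg = tw.TideConfig(constituents=[tw.M2, tw.S2], duration=180, sampling_interval=10)
    return tw.generate_water_level(cfg)


@pytest.fixture(scope="session")
def quiet_ecosystem_60d():
    """Noise-free, quench-free ecosystem driven by an M2+S2 tide, 60 days."""
    cfg = tw.TideConfig(constituents=[tw.M2, tw.S2], duration=60, sampling_interval=10)
    tide = tw.generate_water_level(cfg)
    params = tw.EcosystemParams(noise_sigma=0.0, quench_amplitude=0.0)
    return tw.generate_ecosystem(tide, params)
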