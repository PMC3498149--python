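"""Tidal forcing series: daily tidal range and the current-speed proxy.

Two derived series summarise the tidal forcing: the daily tidal range
(max - min water level per calendar day), which carries the fortnightly
spring-neap and ~monthly apogee-perigee modulation, and the tidal
current-speed proxy TC = |dW/dt|, whose rectification doubles the
semidiurnal frequency to the quarter-diurnal 6 h 12 min at which turbulent
mixing peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import hourly_average
from .timeseries import TimeSeries

__all__ = ["tidal_range", "tidal_current_speed"]


def tidal_range(water_level: TimeSeries) -> TimeSeries:
    """Daily tidal range: max minus min water level per calendar day.

    Requires sub-hourly-to-hourly cadence (a daily series cannot resolve
    the tide).  Days with less than half their expected sample coverage
    are missing.
    """
    if water_level.step > 60:
        raise ValueError("tidal range requires water-level cadence of at most 1 hour")
    s = water_level.to_pandas()
    bins = s.index.floor("D")
    grouped = s.groupby(bins)
    rng = grouped.max() - grouped.min()
    count = grouped.count()
    expected = 1440.0 / water_level.step
    rng[count < 0.5 * expected] = np.nan
    full = pd.date_range(bins[0], bins[-1], freq="D")
    rng = rng.reindex(full)
    return TimeSeries(full[0], 1440.0, rng.to_numpy(), "tidal_range", "m")


def tidal_current_speed(
    water_level: TimeSeries, hourly: bool = False
) -> TimeSeries:
    """Current-speed proxy ``TC_t = |W_t - W_{t-1}| / dt`` in metres per hour.

    One sample shorter than the input; missing wherever either water-level
    sample is missing.  With ``hourly=True`` the water level is averaged to
    hourly cadence *before* differencing, which keeps the effective
    timestamps of TC aligned with rate-of-change series derived from other
    hourly-averaged variables (both are then backward differences of
    identically binned means).  With ``hourly=False`` TC is computed at the
    native gauge cadence and can be hourly-averaged afterwards.
    """
    if hourly:
        water_level = hourly_average(water_level)
    if len(water_level) < 2:
        raise ValueError("need at least two samples to difference")
    dt_h = water_level.step / 60.0
    tc = np.abs(np.diff(water_level.values)) / dt_h
    return TimeSeries(
        water_level.times[1], water_level.step, tc, "tidal_current_speed", "m h-1"
    )
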