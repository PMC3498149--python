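"""Uniformly sampled time series with explicit missing values.

Every stage of the pipeline exchanges :class:`TimeSeries` objects: a start
timestamp, a fixed step in minutes, and a float array in which ``NaN`` marks
a missing observation.  Timestamps are implied (``start_time + k * step``),
which keeps arithmetic on co-registered series trivial and makes uniformity
a structural guarantee rather than a runtime check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "overlap"]


@dataclass
class TimeSeries:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    start_time : pandas.Timestamp
        Timestamp of the first sample.
    step : float
        Sampling interval in minutes (> 0).
    values : numpy.ndarray
        Float array; ``NaN`` marks missing samples.
    variable, units : str
        Labels carried through the pipeline (e.g. ``"chlorophyll"``,
        ``"mg m-3"``).
    """

    start_time: pd.Timestamp
    step: float
    values: np.ndarray
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.values) < 1:
            raise ValueError("series must contain at least one sample")
        if not self.step > 0:
            raise ValueError("step must be positive (minutes)")

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time,
            periods=len(self.values),
            freq=pd.to_timedelta(self.step, unit="m"),
        )

    @property
    def end_time(self) -> pd.Timestamp:
        return self.times[-1]

    def isna(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "TimeSeries":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray, **labels) -> "TimeSeries":
        """A copy sharing the time grid but holding new values."""
        out = replace(self, values=np.asarray(values, dtype=float), **labels)
        return out

    # -- pandas interoperability --------------------------------------------------
    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.times, name=self.variable or None)

    @classmethod
    def from_pandas(
        cls, s: pd.Series, variable: str = "", units: str = ""
    ) -> "TimeSeries":
        """Build from a pandas Series with a uniform DatetimeIndex."""
        idx = pd.DatetimeIndex(s.index)
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == deltas[0]):
                raise ValueError("index is not uniformly spaced")
            step = deltas[0] / 60e9
        else:
            raise ValueError("cannot infer cadence from a single sample")
        return cls(idx[0], float(step), s.to_numpy(dtype=float), variable, units)

    def slice(self, start: int, stop: int) -> "TimeSeries":
        """Sample-index slice as a new series (copy)."""
        if not (0 <= start < stop <= len(self)):
            raise IndexError("invalid slice bounds")
        return TimeSeries(
            self.times[start],
            self.step,
            self.values[start:stop].copy(),
            self.variable,
            self.units,
        )


def overlap(x: TimeSeries, y: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Trim two same-cadence series to their common time window.

    The series must share the sampling step and lie on the same grid (their
    start times differing by an integer number of steps).
    """
    if x.step != y.step:
        raise ValueError(f"cadence mismatch: {x.step} vs {y.step} minutes")
    off = (y.start_time - x.start_time) / pd.to_timedelta(x.step, unit="m")
    if abs(off - round(off)) > 1e-9:
        raise ValueError("series are not on a common time grid")
    start = max(x.start_time, y.start_time)
    end = min(x.end_time, y.end_time)
    if start > end:
        raise ValueError("series do not overlap in time")
    step = pd.to_timedelta(x.step, unit="m")
    ix = int(round((start - x.start_time) / step))
    iy = int(round((start - y.start_time) / step))
    n = int(round((end - start) / step)) + 1
    return x.slice(ix, ix + n), y.slice(iy, iy + n)
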