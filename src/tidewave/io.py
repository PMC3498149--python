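"""CSV reading/writing of time series.

The interchange format is deliberately plain: a header row, an ISO-8601
timestamp column and one value column, missing values as empty fields —
the shape in which buoy telemetry is typically distributed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "write_truth"]


def read_timeseries(path, variable: str | None = None, units: str = "") -> TimeSeries:
    """Read a timestamp+value CSV into a :class:`TimeSeries`.

    The cadence is inferred from the median timestamp difference.  Slightly
    irregular timestamps are snapped to the inferred grid when within half
    a step of it; anything farther off is an error, as are unparseable or
    non-monotone timestamps.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a timestamp column and a value column")
    tcol = df.columns[0]
    vcol = variable if variable in df.columns else df.columns[1]
    try:
        times = pd.to_datetime(df[tcol], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp: {exc}") from None
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two rows to infer cadence")
    deltas = np.diff(times.to_numpy().astype("datetime64[ns]").astype(np.int64))
    if np.any(deltas <= 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    step_ns = float(np.median(deltas))
    if step_ns <= 0:
        raise ValueError(f"{path}: ambiguous cadence")
    # snap to the grid implied by the first timestamp and the median step
    t0 = times.iloc[0].value
    k = (times.to_numpy().astype("datetime64[ns]").astype(np.int64) - t0) / step_ns
    k_round = np.round(k)
    if np.any(np.abs(k - k_round) > 0.5 - 1e-9):
        raise ValueError(f"{path}: timestamps deviate more than half a step from a uniform grid")
    if len(np.unique(k_round)) != len(k_round):
        raise ValueError(f"{path}: ambiguous cadence (two rows snap to the same grid point)")
    n = int(k_round[-1]) + 1
    values = np.full(n, np.nan)
    values[k_round.astype(int)] = pd.to_numeric(df[vcol], errors="coerce").to_numpy()
    return TimeSeries(
        pd.Timestamp(t0), step_ns / 60e9, values, variable or str(vcol), units
    )


def write_timeseries(series: TimeSeries, path) -> None:
    """Write a series as `time,<variable>` CSV with empty fields for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = series.variable or "value"
    with open(path, "w") as fh:
        fh.write(f"time,{name}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t.isoformat()},{'' if np.isnan(v) else repr(float(v))}\n")


def write_truth(truth: dict, path) -> None:
    """Write the ground-truth sidecar of a synthetic dataset as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
        fh.write("\n")
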