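"""Preprocessing: averaging, gap handling, rate-of-change transform, segmentation.

The analysis operates on relative rates of change rather than raw
concentrations: log-transform, 3-point moving average, then first
difference.  Because of the logarithm the difference is a relative
("specific") growth rate, scale-invariant and robust to isolated peaks.

Averaging rules: chlorophyll daily means use dark samples only (PAR below
a threshold) to exclude non-photochemical quenching; other variables use
all valid samples.  Bins with less than half their expected coverage are
marked missing so a stray sample cannot represent an hour or a day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "hourly_average",
    "daily_average",
    "fill_small_gaps",
    "log_smooth_diff",
    "segment",
    "Segment",
    "kd_from_par",
    "chl_spm_contribution",
    "DEFAULT_DARK_THRESHOLD",
    "MIN_SEGMENT_HOURLY",
    "MIN_SEGMENT_DAILY",
]

#: PAR (umol quanta m^-2 s^-1) below which a sample counts as "dark".
DEFAULT_DARK_THRESHOLD = 1.0
#: Segments must contain strictly more than 100 consecutive hourly samples.
MIN_SEGMENT_HOURLY = 101
#: ... and strictly more than 60 consecutive daily samples.
MIN_SEGMENT_DAILY = 61


def _binned_average(
    raw: TimeSeries, freq: str, bin_minutes: float, min_coverage: float = 0.5
) -> TimeSeries:
    """Mean per time bin, missing when under *min_coverage* of expected samples."""
    s = raw.to_pandas()
    bins = s.index.floor(freq)
    grouped = s.groupby(bins)
    mean = grouped.mean()
    count = grouped.count()
    expected = bin_minutes / raw.step
    mean[count < min_coverage * expected] = np.nan
    full = pd.date_range(bins[0], bins[-1], freq=freq)
    mean = mean.reindex(full)
    return TimeSeries(full[0], bin_minutes, mean.to_numpy(), raw.variable, raw.units)


def hourly_average(raw: TimeSeries) -> TimeSeries:
    """One sample per clock hour: mean of valid samples in [h, h+1).

    Hours covered by fewer than half their expected samples are missing.
    """
    if raw.step > 60:
        raise ValueError("cannot compute hourly averages from cadence > 60 min")
    if 60 % raw.step != 0:
        raise ValueError("sampling interval must divide 60 minutes")
    return _binned_average(raw, "h", 60.0)


def daily_average(
    raw: TimeSeries,
    par: TimeSeries | None = None,
    dark_threshold: float = DEFAULT_DARK_THRESHOLD,
) -> TimeSeries:
    """One sample per calendar day.

    For chlorophyll (``raw.variable == "chlorophyll"``) the mean is taken
    over samples measured in the dark (simultaneous PAR < *dark_threshold*),
    removing the daytime quenching artefact; a day with no dark sample is
    missing.  All other variables average every valid sample, with the
    half-coverage rule.
    """
    is_chl = raw.variable == "chlorophyll"
    if is_chl:
        if par is None:
            raise ValueError("daily chlorophyll averages require a co-registered PAR series")
        if par.step != raw.step or par.start_time != raw.start_time or len(par) != len(raw):
            raise ValueError("PAR series is not co-registered with chlorophyll")
        vals = np.where(par.values < dark_threshold, raw.values, np.nan)
        masked = raw.with_values(vals)
        s = masked.to_pandas()
        bins = s.index.floor("D")
        mean = s.groupby(bins).mean()  # NaN when no dark sample qualifies
        full = pd.date_range(bins[0], bins[-1], freq="D")
        mean = mean.reindex(full)
        return TimeSeries(full[0], 1440.0, mean.to_numpy(), raw.variable, raw.units)
    return _binned_average(raw, "D", 1440.0)


def fill_small_gaps(series: TimeSeries) -> TimeSeries:
    """Fill isolated single missing samples by linear interpolation.

    Runs of two or more missing samples, and missing samples at the series
    boundaries, are left untouched.  Never alters a valid sample.
    """
    v = series.values.copy()
    nan = np.isnan(v)
    idx = np.flatnonzero(nan[1:-1]) + 1
    for i in idx:
        if not nan[i - 1] and not nan[i + 1]:
            v[i] = 0.5 * (v[i - 1] + v[i + 1])
    return series.with_values(v)


def log_smooth_diff(series: TimeSeries) -> TimeSeries:
    """Three-step transform to relative rates of change.

    1. natural log; 2. centred 3-point moving average (windows touching a
    missing value or a boundary yield missing); 3. first difference
    ``r_t = z_t - z_{t-1}``.  The result is one sample shorter than the
    input and unitless (per step).

    Raises
    ------
    ValueError
        If any valid sample is non-positive (the log is undefined); the
        message names the first offending index.
    """
    v = series.values
    bad = np.flatnonzero(~np.isnan(v) & (v <= 0))
    if bad.size:
        raise ValueError(
            f"log transform undefined: non-positive value {v[bad[0]]!r} at index {int(bad[0])}"
        )
    y = np.log(v)
    z = np.full_like(y, np.nan)
    z[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0  # NaN propagates through the window
    r = z[1:] - z[:-1]
    out = TimeSeries(
        series.times[1],
        series.step,
        r,
        f"rate_of_change({series.variable})" if series.variable else "rate_of_change",
        "per step",
    )
    return out


class Segment:
    """A maximal gap-free run of samples: ``series.values[start:start+length]``."""

    __slots__ = ("start_index", "length")

    def __init__(self, start_index: int, length: int):
        self.start_index = int(start_index)
        self.length = int(length)

    def __repr__(self) -> str:
        return f"Segment(start_index={self.start_index}, length={self.length})"

    def __eq__(self, other) -> bool:
        return (self.start_index, self.length) == (other.start_index, other.length)

    def extract(self, series: TimeSeries) -> TimeSeries:
        return series.slice(self.start_index, self.start_index + self.length)


def segment(series: TimeSeries, min_length: int) -> list[Segment]:
    """All maximal gap-free runs of at least *min_length* samples, in order.

    With the conventional thresholds (:data:`MIN_SEGMENT_HOURLY` = 101,
    :data:`MIN_SEGMENT_DAILY` = 61) a run of exactly 100 hourly or 60 daily
    samples is rejected: usable subsets must exceed those lengths strictly,
    so that detected periods up to ~25% of the segment length remain
    trustworthy.
    """
    if min_length < 1:
        raise ValueError("min_length must be at least 1")
    valid = ~np.isnan(series.values)
    out: list[Segment] = []
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            if j - i >= min_length:
                out.append(Segment(i, j - i))
            i = j
        else:
            i += 1
    return out


def kd_from_par(par_1m: TimeSeries, par_2m: TimeSeries) -> TimeSeries:
    """Diffuse attenuation coefficient from irradiance at 1 m and 2 m depth.

    ``Kd = ln(I1/I2) / (2 m - 1 m)`` per metre; samples with non-positive
    irradiance at either depth are missing.
    """
    if (
        par_1m.step != par_2m.step
        or par_1m.start_time != par_2m.start_time
        or len(par_1m) != len(par_2m)
    ):
        raise ValueError("PAR series must be co-registered")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = par_1m.values / par_2m.values
        kd = np.where((par_1m.values > 0) & (par_2m.values > 0), np.log(ratio), np.nan)
    return par_1m.with_values(kd, variable="kd", units="m-1")


def chl_spm_contribution(
    chlorophyll: float | np.ndarray,
    biomass_carbon_ratio: float = 2.5,
    carbon_chl_ratio: float = 40.0,
):
    """SPM-equivalent mass of the phytoplankton standing stock.

    ``chl * (biomass / carbon) * (carbon / chl)``; with the default ratios
    (2.5 and 40, appropriate for marine diatoms in nutrient-rich temperate
    waters) one mg m^-3 of chlorophyll contributes 100 mg m^-3 of SPM.
    """
    chl = np.asarray(chlorophyll, dtype=float)
    if np.any(chl < 0) or biomass_carbon_ratio < 0 or carbon_chl_ratio < 0:
        raise ValueError("chlorophyll and conversion ratios must be non-negative")
    out = chl * biomass_carbon_ratio * carbon_chl_ratio
    return float(out) if np.isscalar(chlorophyll) else out
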