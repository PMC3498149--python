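"""Wavelet coherence, phase angles, and Monte-Carlo red-noise significance.

Squared wavelet coherence is a localised correlation coefficient in
time-frequency space:

    R2(s, t) = |S(W_xy / s)|**2 / ( S(|W_x|**2 / s) * S(|W_y|**2 / s) )

where ``W_xy = W_x * conj(W_y)`` is the cross-wavelet spectrum and ``S`` is
smoothing in time (Gaussian with standard deviation equal to the scale)
followed by smoothing across scales (boxcar of ~0.6 octaves).  The phase of
the smoothed cross-spectrum encodes lead/lag; with the convention used here
a positive phase means the first series leads the second, so a phase of
``-360 * L / P`` degrees (equivalently ``360 - 360*L/P`` on the circle)
means the first series lags the second by ``L`` at period ``P``.

Significance of R2 has no convenient closed form, so it is assessed by
Monte Carlo: per-scale 95% quantiles of coherence between pairs of AR(1)
surrogates matched to the two series in length and lag-1 autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter
from scipy.stats import circmean, circstd

from .timeseries import TimeSeries
from .wavelet import WaveletParams, estimate_ar1, morlet_cwt

__all__ = [
    "CoherenceSpectrum",
    "PhaseHistogram",
    "wavelet_coherence",
    "mc_coherence_significance",
    "phase_distribution",
    "phase_to_lag",
    "lag_to_phase",
]

#: Width of the scale-direction boxcar smoother, in octaves.
SCALE_SMOOTH_OCTAVES = 0.6


@dataclass
class CoherenceSpectrum:
    """Squared coherence and phase over (scale, time)."""

    scales: np.ndarray
    fourier_periods: np.ndarray  # minutes
    times: pd.DatetimeIndex
    r2: np.ndarray  # in [0, 1]
    phase: np.ndarray  # degrees, signed in (-180, 180]
    coi: np.ndarray  # minutes
    dt: float
    params: WaveletParams
    signif_mask: np.ndarray | None = None
    signif_threshold: np.ndarray | None = None  # per-scale R2 threshold
    source: tuple[str, str] = ("x", "y")

    def outside_coi(self) -> np.ndarray:
        return self.fourier_periods[:, None] <= self.coi[None, :]

    def phase_unsigned(self) -> np.ndarray:
        """Phase mapped to [0, 360) degrees, the plotting convention."""
        return np.mod(self.phase, 360.0)


def _smooth(field: np.ndarray, scales: np.ndarray, dt: float, dj: float) -> np.ndarray:
    """Time smoothing (Gaussian, sigma = scale) then scale smoothing (boxcar).

    The Gaussian convolution is applied in the frequency domain on a
    zero-padded copy (linear convolution; the series is treated as zero
    outside its support, which attenuates numerator and denominators of the
    coherence ratio alike near the edges).
    """
    n = field.shape[1]
    m = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2 * np.pi * np.fft.fftfreq(m)  # radians per sample
    fhat = np.fft.fft(field, m, axis=1)
    sigma = (scales / dt)[:, None]  # samples
    kernel = np.exp(-0.5 * (sigma * omega[None, :]) ** 2)
    out = np.fft.ifft(fhat * kernel, axis=1)[:, :n]
    if np.isrealobj(field):
        out = out.real
    width = max(1, int(round(SCALE_SMOOTH_OCTAVES / dj)))
    if width > 1:
        if np.iscomplexobj(out):
            out = uniform_filter1d(out.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(out.imag, width, axis=0, mode="nearest")
        else:
            out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def _coherence_matrices(
    x: np.ndarray, y: np.ndarray, dt: float, start, params: WaveletParams
):
    xs = TimeSeries(start, dt, x)
    ys = TimeSeries(start, dt, y)
    cx = morlet_cwt(xs, params)
    cy = morlet_cwt(ys, params)
    s_col = cx.scales[:, None]
    dj = params.dj
    sxx = _smooth(cx.power / s_col, cx.scales, dt, dj).real
    syy = _smooth(cy.power / s_col, cx.scales, dt, dj).real
    wxy = cx.coefficients * np.conj(cy.coefficients) / s_col
    sxy = _smooth(wxy, cx.scales, dt, dj)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    phase = np.degrees(np.angle(sxy))
    return cx, r2, phase


def wavelet_coherence(
    x: TimeSeries, y: TimeSeries, params: WaveletParams | None = None
) -> CoherenceSpectrum:
    """Squared wavelet coherence and phase of two co-registered series.

    Positive phase means *x* leads *y*; 0 degrees (arrows right in the
    conventional plots) means in-phase fluctuation.
    """
    params = params or WaveletParams()
    if x.step != y.step:
        raise ValueError("series must share the sampling cadence")
    if len(x) != len(y) or x.start_time != y.start_time:
        raise ValueError("series must be co-registered (same start and length)")
    xv, yv = np.asarray(x.values, float), np.asarray(y.values, float)
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("series must be gap-free; apply segmentation first")
    cx, r2, phase = _coherence_matrices(xv, yv, x.step, x.start_time, params)
    return CoherenceSpectrum(
        scales=cx.scales,
        fourier_periods=cx.fourier_periods,
        times=x.times,
        r2=r2,
        phase=phase,
        coi=cx.coi,
        dt=x.step,
        params=params,
        source=(x.variable or "x", y.variable or "y"),
    )


def _ar1_surrogate(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """AR(1) sequence with unit marginal variance (stationary start)."""
    eps = rng.standard_normal(n) * np.sqrt(1 - alpha**2)
    eps[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -alpha], eps)


def mc_coherence_significance(
    x: TimeSeries,
    y: TimeSeries,
    spec: CoherenceSpectrum,
    n_surrogates: int = 300,
    seed: int = 0,
    level: float = 0.95,
) -> CoherenceSpectrum:
    """Monte-Carlo red-noise significance for a coherence spectrum.

    Coherence of *n_surrogates* pairs of AR(1) surrogates (lag-1
    autocorrelations fitted from *x* and *y*, matched length) yields a
    per-scale null distribution of R2, pooled over time points outside the
    cone of influence; the *level* quantile becomes the per-scale
    threshold.  Reproducible for a fixed *seed*.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogate pairs for a stable quantile")
    ax = estimate_ar1(x).alpha
    ay = estimate_ar1(y).alpha
    n = len(x)
    rng = np.random.default_rng(seed)
    n_scales = len(spec.scales)
    outside = spec.outside_coi()
    samples: list[np.ndarray] = []
    # Pool per-scale R2 values over surrogates and (outside-COI) time points.
    pools = [[] for _ in range(n_scales)]
    for _ in range(n_surrogates):
        sx = _ar1_surrogate(rng, n, ax)
        sy = _ar1_surrogate(rng, n, ay)
        _, r2s, _ = _coherence_matrices(sx, sy, spec.dt, x.start_time, spec.params)
        for j in range(n_scales):
            vals = r2s[j, outside[j]]
            if vals.size:
                pools[j].append(vals.astype(np.float32))
    threshold = np.full(n_scales, np.inf)
    for j in range(n_scales):
        if pools[j]:
            threshold[j] = np.quantile(np.concatenate(pools[j]), level)
    spec.signif_threshold = threshold
    spec.signif_mask = (spec.r2 > threshold[:, None]) & outside
    return spec


@dataclass
class PhaseHistogram:
    """Distribution of significant phase angles within a period band."""

    bin_edges: np.ndarray  # degrees, [0, 360]
    counts: np.ndarray
    band: tuple[float, float]  # minutes
    source: tuple[str, str]
    circular_mean: float  # degrees in [0, 360), NaN if empty
    circular_std: float  # degrees, NaN if empty
    empty: bool = False

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def phase_distribution(
    spec: CoherenceSpectrum, band: tuple[float, float], bin_width: float = 20.0
) -> PhaseHistogram:
    """Histogram of significant phase angles in a period band.

    Pools the phase of every cell that is significant, within *band*
    (minutes), and outside the cone of influence; angles are reported on
    [0, 360) with the circular mean and circular standard deviation.  An
    empty selection returns an empty histogram flagged ``empty=True``.
    """
    if spec.signif_mask is None:
        raise ValueError("run mc_coherence_significance first")
    if 360.0 % bin_width != 0:
        raise ValueError("bin_width must divide 360 degrees")
    lo, hi = band
    in_band = (spec.fourier_periods >= lo) & (spec.fourier_periods <= hi)
    sel = spec.signif_mask & in_band[:, None] & spec.outside_coi()
    angles = np.mod(spec.phase[sel], 360.0)
    angles = np.where(angles >= 360.0 - 1e-6, 0.0, angles)  # 360 == 0 on the circle
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    if angles.size == 0:
        return PhaseHistogram(edges, counts, band, spec.source, np.nan, np.nan, empty=True)
    cm = float(np.mod(circmean(angles, high=360.0), 360.0))
    cs = float(circstd(angles, high=360.0))
    return PhaseHistogram(edges, counts, band, spec.source, cm, cs)


def phase_to_lag(phase: float, period: float) -> float:
    """Time by which the first series lags the second, minutes.

    With positive phase meaning "x leads y", a phase just below 360 degrees
    is a small lag of x behind y: ``lag = ((360 - phase) mod 360)/360 * period``.
    """
    if not period > 0:
        raise ValueError("period must be positive")
    return ((360.0 - phase) % 360.0) / 360.0 * period


def lag_to_phase(lag: float, period: float) -> float:
    """Inverse of :func:`phase_to_lag`: phase angle in [0, 360)."""
    if not period > 0:
        raise ValueError("period must be positive")
    return (360.0 - 360.0 * lag / period) % 360.0
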