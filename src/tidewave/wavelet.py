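"""Morlet continuous wavelet transform with red-noise significance.

The transform follows the standard frequency-domain formulation: the mother
wavelet is ``psi0(eta) = pi**-0.25 * exp(i*omega0*eta) * exp(-eta**2/2)``
with ``omega0 = 6``, scales form a geometric ladder ``s_j = s0 * 2**(j*dj)``,
and the wavelet coefficients are computed by inverse FFT of the product of
the (zero-padded) signal spectrum with the scaled wavelet spectrum.  The
scale-to-period conversion is ``lambda = 4*pi*s / (omega0 + sqrt(2 +
omega0**2))`` (factor ~1.033 for omega0 = 6) and the cone of influence is
the e-folding distance ``sqrt(2)*s`` of the wavelet envelope, mapped to
period units.

Pointwise significance tests wavelet power against the theoretical spectrum
of an AR(1) ("red noise") process with the lag-1 autocorrelation of the
data: power exceeding ``sigma**2 * P_k * chi2_2(level) / 2`` is significant.
Global (time-averaged) spectra use the chi-square approximation with
degrees of freedom growing with the number of independent time points per
scale (decorrelation factor gamma = 2.32 for the Morlet).

Power is stored un-rescaled (|W|**2); a scale-normalised view for plotting
is available via :meth:`WaveletSpectrum.scale_normalised_power`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .timeseries import TimeSeries

__all__ = [
    "WaveletParams",
    "WaveletSpectrum",
    "RedNoiseModel",
    "GlobalSpectrum",
    "OMEGA0",
    "fourier_factor",
    "morlet_cwt",
    "estimate_ar1",
    "rednoise_significance",
    "global_spectrum",
    "peak_period",
]

#: Nondimensional frequency of the Morlet carrier wave.
OMEGA0 = 6.0
#: Decorrelation-length factor for time-averaged significance (Morlet).
GAMMA_MORLET = 2.32
#: Reconstruction constant C_delta for the Morlet wavelet at omega0 = 6.
C_DELTA_MORLET = 0.776


def fourier_factor(omega0: float = OMEGA0) -> float:
    """Ratio of equivalent Fourier period to wavelet scale (~1.033 at omega0=6)."""
    return 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))


@dataclass
class WaveletParams:
    """Transform configuration.

    ``s0`` (smallest scale, minutes) defaults to twice the sampling step;
    ``n_scales`` defaults to a ladder reaching ~25% of the segment length,
    the detection limit beyond which a period never leaves the cone of
    influence.  ``pad_factor`` controls zero padding: the series is padded
    to the next power of two at least ``pad_factor`` times its length,
    keeping the FFT a linear (not circular) convolution.
    """

    omega0: float = OMEGA0
    dj: float = 1.0 / 24.0
    s0: float | None = None  # minutes; None -> 2 * dt
    n_scales: int | None = None  # None -> up to 25% of segment length
    pad: bool = True
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for practical admissibility")
        if not self.dj > 0:
            raise ValueError("dj must be positive")

    def scales(self, n: int, dt: float) -> np.ndarray:
        s0 = 2.0 * dt if self.s0 is None else self.s0
        if s0 < dt:
            raise ValueError("smallest scale must be at least the sampling step")
        if self.n_scales is None:
            s_max = 0.25 * n * dt  # detection limit
            j_max = int(np.floor(np.log2(s_max / s0) / self.dj))
            j_max = max(j_max, 1)
        else:
            j_max = self.n_scales - 1
        return s0 * 2.0 ** (self.dj * np.arange(j_max + 1))


@dataclass
class WaveletSpectrum:
    """Local wavelet power over (scale, time) for one gap-free segment."""

    scales: np.ndarray  # minutes
    fourier_periods: np.ndarray  # minutes
    times: pd.DatetimeIndex
    coefficients: np.ndarray  # complex, (n_scales, n_times)
    power: np.ndarray  # |W|^2, (n_scales, n_times)
    coi: np.ndarray  # per-time maximum trustworthy period, minutes
    dt: float  # minutes
    variance: float  # variance of the (demeaned) segment
    params: WaveletParams
    signif_mask: np.ndarray | None = None
    alpha: float | None = None

    @property
    def n_times(self) -> int:
        return self.power.shape[1]

    def outside_coi(self) -> np.ndarray:
        """Boolean (scale, time) matrix, True where the period is trustworthy."""
        return self.fourier_periods[:, None] <= self.coi[None, :]

    def scale_normalised_power(self) -> np.ndarray:
        """Bias-corrected power |W|^2 / s, for plotting only."""
        return self.power / self.scales[:, None]


def _morlet_fft(s_omega: np.ndarray, omega0: float) -> np.ndarray:
    """Fourier transform of the Morlet mother wavelet on the positive axis."""
    out = np.zeros_like(s_omega)
    pos = s_omega > 0
    out[pos] = np.pi**-0.25 * np.exp(-((s_omega[pos] - omega0) ** 2) / 2.0)
    return out


def morlet_cwt(seg: TimeSeries, params: WaveletParams | None = None) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform of a gap-free segment.

    The segment mean is removed internally; coefficients are normalised so
    that for white noise the expected power equals the series variance at
    every scale.
    """
    params = params or WaveletParams()
    x = np.asarray(seg.values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("segment contains missing values; apply segmentation first")
    n = len(x)
    if n < 4:
        raise ValueError("segment too short for wavelet analysis (need >= 4 samples)")
    dt = seg.step
    x = x - x.mean()
    variance = float(x.var())

    if params.pad:
        m = int(2 ** np.ceil(np.log2(max(params.pad_factor, 1) * n)))
    else:
        m = n
    xhat = np.fft.fft(x, m)
    omega = 2 * np.pi * np.fft.fftfreq(m, d=dt)  # radians per minute

    scales = params.scales(n, dt)
    # (n_scales, m) wavelet spectra; normalisation sqrt(2*pi*s/dt) gives
    # unit expected power for unit-variance white noise.
    psi = _morlet_fft(scales[:, None] * omega[None, :], params.omega0)
    psi *= np.sqrt(2 * np.pi * scales[:, None] / dt)
    W = np.fft.ifft(xhat[None, :] * psi, axis=1)[:, :n]

    ff = fourier_factor(params.omega0)
    periods = ff * scales
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = ff / np.sqrt(2.0) * dt * np.maximum(edge, 1e-9)

    return WaveletSpectrum(
        scales=scales,
        fourier_periods=periods,
        times=seg.times,
        coefficients=W,
        power=np.abs(W) ** 2,
        coi=coi,
        dt=dt,
        variance=variance,
        params=params,
    )


@dataclass
class RedNoiseModel:
    """AR(1) null model fitted to a segment."""

    alpha: float
    variance: float

    def background(self, freq: np.ndarray) -> np.ndarray:
        """Normalised theoretical AR(1) spectrum at *freq* cycles per sample.

        ``P = (1 - alpha^2) / (1 + alpha^2 - 2*alpha*cos(2*pi*f))``, which has
        unit mean over frequency (flat at 1 for white noise).
        """
        a = self.alpha
        return (1.0 - a**2) / (1.0 + a**2 - 2.0 * a * np.cos(2.0 * np.pi * np.asarray(freq)))


def estimate_ar1(seg: TimeSeries) -> RedNoiseModel:
    """Lag-1 autocorrelation and variance of a gap-free, non-constant segment."""
    x = np.asarray(seg.values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("segment contains missing values")
    if len(x) < 3:
        raise ValueError("need at least 3 samples to estimate lag-1 autocorrelation")
    x = x - x.mean()
    denom = np.sum(x * x)
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    alpha = float(np.sum(x[1:] * x[:-1]) / denom)
    alpha = float(np.clip(alpha, 0.0, 0.999))
    return RedNoiseModel(alpha=alpha, variance=float(np.var(x)))


def rednoise_significance(
    spec: WaveletSpectrum, model: RedNoiseModel, level: float = 0.95
) -> WaveletSpectrum:
    """Attach a pointwise red-noise significance mask to a spectrum.

    The local power at each scale is chi-square distributed with 2 degrees
    of freedom about the AR(1) background at the scale's equivalent Fourier
    frequency; cells exceeding the *level* quantile and lying outside the
    cone of influence are flagged.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    freq = spec.dt / spec.fourier_periods  # cycles per sample
    pk = model.background(freq)
    threshold = model.variance * pk * chi2.ppf(level, 2) / 2.0
    mask = (spec.power > threshold[:, None]) & spec.outside_coi()
    spec.signif_mask = mask
    spec.alpha = model.alpha
    return spec


@dataclass
class GlobalSpectrum:
    """Time-averaged wavelet power with a red-noise 95% curve."""

    fourier_periods: np.ndarray  # minutes
    mean_power: np.ndarray
    signif: np.ndarray  # per-period threshold at the requested level
    n_timepoints: int
    level: float = 0.95


def global_spectrum(
    spectra: list[WaveletSpectrum],
    model: RedNoiseModel | None = None,
    level: float = 0.95,
) -> GlobalSpectrum:
    """Average local power per period over the time points of all segments.

    Every time point of every segment contributes equally, so longer
    segments carry proportionally more weight.  The significance curve uses
    the time-averaged chi-square approximation ``nu = 2 * sqrt(1 +
    (n*dt/(gamma*s))**2)`` with the total number of contributing time points.
    If *model* is omitted it is fitted to the concatenated segments.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for sp in spectra[1:]:
        if len(sp.scales) != len(ref.scales) or not np.allclose(sp.scales, ref.scales):
            raise ValueError("all spectra must share the same scale grid")
        if sp.dt != ref.dt:
            raise ValueError("all spectra must share the sampling step")

    total = np.zeros(len(ref.scales))
    n_total = 0
    for sp in spectra:
        total += sp.power.sum(axis=1)
        n_total += sp.n_times
    mean_power = total / n_total

    if model is None:
        # Fall back to segment-level fits; callers normally pass a model.
        alpha = float(np.mean([sp.alpha for sp in spectra if sp.alpha is not None] or [0.0]))
        variance = float(np.average([sp.variance for sp in spectra], weights=[sp.n_times for sp in spectra]))
        model = RedNoiseModel(alpha=alpha, variance=variance)

    freq = ref.dt / ref.fourier_periods
    pk = model.background(freq)
    dof = 2.0 * np.sqrt(1.0 + (n_total * ref.dt / (GAMMA_MORLET * ref.scales)) ** 2)
    signif = model.variance * pk * chi2.ppf(level, dof) / dof
    return GlobalSpectrum(
        fourier_periods=ref.fourier_periods.copy(),
        mean_power=mean_power,
        signif=signif,
        n_timepoints=n_total,
        level=level,
    )


def peak_period(
    gs: GlobalSpectrum, band: tuple[float, float] | None = None
) -> tuple[float, bool]:
    """Period (minutes) of the global-spectrum maximum, parabolically refined.

    The peak bin and its two neighbours are fitted with a parabola in
    (log2 period, power); the vertex gives sub-bin resolution.  Ties break
    toward the shorter period.  Returns ``(period, at_boundary)``: when the
    maximum sits on the edge of the band (or scale range) the raw bin
    period is returned with ``at_boundary=True``.
    """
    periods = gs.fourier_periods
    power = gs.mean_power
    if band is not None:
        lo, hi = band
        if not lo < hi:
            raise ValueError("empty period band")
        sel = (periods >= lo) & (periods <= hi)
        if not sel.any():
            raise ValueError("band contains no scale bins")
        idx = np.flatnonzero(sel)
    else:
        idx = np.arange(len(periods))
    k_local = int(np.argmax(power[idx]))  # first max -> shorter period on ties
    k = idx[k_local]
    if k_local == 0 or k_local == len(idx) - 1 or k == 0 or k == len(periods) - 1:
        return float(periods[k]), True
    lp = np.log2(periods[k - 1 : k + 2])
    y = power[k - 1 : k + 2]
    denom = y[0] - 2 * y[1] + y[2]
    if denom == 0:
        return float(periods[k]), False
    delta = 0.5 * (y[0] - y[2]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (lp[2] - lp[0])
    return float(2.0 ** (lp[1] + delta * step)), False
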