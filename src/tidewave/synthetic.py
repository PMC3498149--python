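"""Synthetic mooring data with known ground truth.

Generates tidal water levels from harmonic constituents and a bundle of
co-varying series (SPM, chlorophyll fluorescence, salinity, nitrate,
temperature, PAR) that reproduce the phase structure observed at shallow,
well-mixed coastal stations of the southern North Sea:

* a semidiurnal (M2, 12 h 25 min) tide whose interference with S2 and N2
  produces the ~14.77 d spring-neap and ~27.5 d apogee-perigee modulation
  of the tidal range;
* SPM driven by resuspension proportional to the square of the tidal
  current speed (quarter-diurnal, 6 h 12 min) with a short entrainment
  delay, balanced by settling;
* chlorophyll fluorescence composed of a resuspended ("tychoplankton")
  fraction proportional to SPM plus a light-limited growth pool, with
  optional daytime non-photochemical quenching locked to the 24.000 h
  solar cycle;
* salinity in phase and nitrate in anti-phase with water level (estuarine
  exchange at the semidiurnal period);
* an optional bloom window during which resuspension weakens, SPM settles
  out, light improves, and the growth pool escapes the tidal regime.

All randomness is multiplicative lognormal AR(1) observation noise (plus
small additive noise on temperature and salinity) reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .timeseries import TimeSeries

__all__ = [
    "HarmonicConstituent",
    "TideConfig",
    "EcosystemParams",
    "SyntheticDataset",
    "M2",
    "S2",
    "N2",
    "default_constituents",
    "beat_period",
    "generate_water_level",
    "generate_ecosystem",
    "inject_gaps",
]


@dataclass(frozen=True)
class HarmonicConstituent:
    """A single tidal harmonic: ``A * cos(2*pi*t/T + phi)``."""

    name: str
    amplitude: float  # metres
    period: float  # minutes
    phase: float = 0.0  # radians in [0, 2*pi)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not (0 <= self.phase < 2 * np.pi):
            raise ValueError("phase must lie in [0, 2*pi)")


#: Principal lunar, principal solar and larger lunar elliptic semidiurnal
#: constituents.  Periods are the standard astronomical values; amplitudes
#: are set so the mean daily tidal range is ~4.3 m, typical of the outer
#: Thames estuary.
M2 = HarmonicConstituent("M2", 2.15, 745.2)
S2 = HarmonicConstituent("S2", 0.65, 720.0)
N2 = HarmonicConstituent("N2", 0.42, 759.5)


def default_constituents() -> list[HarmonicConstituent]:
    return [M2, S2, N2]


def beat_period(a: HarmonicConstituent, b: HarmonicConstituent) -> float:
    """Synodic (beat) period of two constituents, in minutes.

    ``1 / |1/Ta - 1/Tb|`` — the period of the amplitude modulation produced
    by their interference: ~14.77 d for M2-S2 (spring-neap), ~27.5 d for
    M2-N2 (apogee-perigee).
    """
    if a.period == b.period:
        raise ValueError("constituents with equal periods do not beat")
    return 1.0 / abs(1.0 / a.period - 1.0 / b.period)


@dataclass
class TideConfig:
    """Configuration for harmonic water-level synthesis."""

    constituents: list[HarmonicConstituent] = field(default_factory=default_constituents)
    start_time: pd.Timestamp = pd.Timestamp("2007-01-01")
    duration: float = 365.0  # days
    sampling_interval: float = 10.0  # minutes; tide gauges report every 10 min
    mean_level: float = 0.0  # metres above datum

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if 60 % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 60 minutes")
        if not self.constituents and self.duration == 0:
            raise ValueError("empty constituent list with zero duration")


def generate_water_level(config: TideConfig) -> TimeSeries:
    """Deterministic harmonic tide: ``W(t) = mean + sum_i A_i cos(2 pi t/T_i + phi_i)``."""
    n = int(round(config.duration * 1440.0 / config.sampling_interval))
    if n < 1:
        raise ValueError("configuration yields an empty series")
    t = np.arange(n) * config.sampling_interval  # minutes since start
    w = np.full(n, float(config.mean_level))
    for c in config.constituents:
        w += c.amplitude * np.cos(2 * np.pi * t / c.period + c.phase)
    return TimeSeries(config.start_time, config.sampling_interval, w, "water_level", "m")


@dataclass
class EcosystemParams:
    """Parameters of the resuspension-settling / growth model.

    Units are stated per field.  SPM concentrations are in mg L^-1,
    chlorophyll in mg m^-3, irradiance in umol quanta m^-2 s^-1, rates
    per hour unless noted.
    """

    #: SPM source per unit squared current speed: mg L^-1 h^-1 per (m h^-1)^2.
    resuspension_coeff: float = 3.3
    #: First-order settling loss towards the background, h^-1.  ~0.1 h^-1
    #: corresponds to aggregate sinking of ~35 m d^-1 over a 15 m column.
    settling_rate: float = 0.1
    #: Permanently suspended fines, mg L^-1.
    spm_background: float = 5.0
    #: Delay between peak current speed and arrival of resuspended material
    #: at the sensor depth, minutes.
    entrainment_delay: float = 45.0
    #: Chlorophyll carried per unit SPM (tychoplankton fraction),
    #: mg chl m^-3 per mg SPM L^-1.
    chl_spm_fraction: float = 0.08
    #: Maximum specific growth rate of the pelagic pool, d^-1.
    growth_rate_max: float = 1.5
    #: Monod half-saturation irradiance, umol quanta m^-2 s^-1.
    light_half_saturation: float = 100.0
    #: SPM-specific light attenuation, m^-1 per mg L^-1.
    kd_per_spm: float = 0.06
    #: Fractional daytime depression of fluorescence yield, in [0, 1).
    quench_amplitude: float = 0.3
    #: (start, end) timestamps of the weak-resuspension bloom window, or None.
    bloom_window: tuple | None = None
    #: Factor applied to resuspension_coeff inside the bloom window.
    bloom_resuspension_factor: float = 0.3
    #: Semidiurnal salinity excursion, psu (in phase with water level).
    salinity_tide_amplitude: float = 0.3
    #: Semidiurnal nitrate excursion, mmol m^-3 (anti-phase with water level).
    nitrate_tide_amplitude: float = 2.0
    #: Lag-1 autocorrelation of the observation-noise AR(1) process.
    noise_ar1_alpha: float = 0.5
    #: Relative (lognormal) noise standard deviation.
    noise_sigma: float = 0.15
    seed: int = 0

    # fixed internal constants (documented, not free parameters)
    kd_water: float = 0.2  # clear-water + CDOM attenuation, m^-1
    loss_rate: float = 0.8  # pelagic-pool loss (grazing + respiration), d^-1
    seed_stock: float = 0.02  # immigration floor of the growth pool, mg m^-3 d^-1
    surface_par_max: float = 1500.0  # clear-sky noon PAR at the surface, summer
    temp_winter: float = 6.1  # degC, mid-February minimum
    temp_summer: float = 18.6  # degC, mid-August maximum
    salinity_mean: float = 34.0  # psu
    nitrate_winter: float = 25.0  # mmol m^-3
    nitrate_summer: float = 5.0  # mmol m^-3

    def __post_init__(self) -> None:
        if not self.settling_rate > 0:
            raise ValueError("settling_rate must be positive")
        if not 0 <= self.quench_amplitude < 1:
            raise ValueError("quench_amplitude must lie in [0, 1)")
        if not 0 <= self.noise_ar1_alpha < 1:
            raise ValueError("noise_ar1_alpha must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    """Co-registered simulated series plus the generating ground truth."""

    water_level: TimeSeries
    chlorophyll: TimeSeries
    spm: TimeSeries
    salinity: TimeSeries
    temperature: TimeSeries
    nitrate: TimeSeries
    par: TimeSeries
    truth: dict

    def series(self) -> dict[str, TimeSeries]:
        return {
            "water_level": self.water_level,
            "chlorophyll": self.chlorophyll,
            "spm": self.spm,
            "salinity": self.salinity,
            "temperature": self.temperature,
            "nitrate": self.nitrate,
            "par": self.par,
        }


def _ar1_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """AR(1) sequence with unit marginal variance (stationary start)."""
    eps = rng.standard_normal(n) * np.sqrt(1.0 - alpha**2)
    eps[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -alpha], eps)


def _daylight(times: pd.DatetimeIndex) -> np.ndarray:
    """Clipped solar elevation proxy with an exactly 24.000 h period, in [0, 1]."""
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    return np.clip(np.cos(2 * np.pi * (hour - 12.0) / 24.0), 0.0, None)


def _season(times: pd.DatetimeIndex, lo: float, hi: float, peak_doy: float = 228.0) -> np.ndarray:
    """Seasonal sinusoid between lo (winter) and hi (summer), peaking at day peak_doy."""
    doy = times.dayofyear.to_numpy() + times.hour.to_numpy() / 24.0
    mid, amp = (hi + lo) / 2.0, (hi - lo) / 2.0
    return mid + amp * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def generate_ecosystem(tide: TimeSeries, params: EcosystemParams) -> SyntheticDataset:
    """Simulate the full mooring bundle driven by a (gap-free) tide.

    SPM obeys the forward-Euler difference equation

        S(t+dt) = S(t) + dt * [ a(t) * TC(t - delay)^2 - lambda * (S(t) - S_bg) ]

    with ``TC = |dW/dt|`` computed internally from the tide, ``a`` the
    resuspension coefficient (reduced inside the bloom window) and
    ``lambda`` the settling rate.  The pelagic chlorophyll pool B grows at a
    Monod rate on PAR attenuated by SPM and loses at a fixed rate; observed
    fluorescence is ``(f*S + B) * (1 - q*daylight)``.
    """
    if np.isnan(tide.values).any():
        raise ValueError("tide must be gap-free; inject gaps after simulation")
    n = len(tide)
    dt_h = tide.step / 60.0  # hours
    times = tide.times
    rng = np.random.default_rng(params.seed)
    streams = {k: np.random.default_rng(s) for k, s in zip(
        ["chl", "spm", "sal", "temp", "nit", "par"], rng.integers(0, 2**31 - 1, 6)
    )}

    # --- tidal current speed proxy, delayed ---------------------------------
    tc = np.empty(n)
    tc[1:] = np.abs(np.diff(tide.values)) / dt_h  # m h^-1
    tc[0] = tc[1]
    lag = int(round(params.entrainment_delay / tide.step))
    tc_del = np.empty(n)
    tc_del[lag:] = tc[: n - lag] if lag > 0 else tc
    tc_del[:lag] = tc[0]

    # --- resuspension coefficient, reduced inside the bloom window ----------
    a = np.full(n, params.resuspension_coeff)
    in_bloom = np.zeros(n, dtype=bool)
    if params.bloom_window is not None:
        b0, b1 = (pd.Timestamp(b) for b in params.bloom_window)
        in_bloom = (times >= b0) & (times <= b1)
        a[in_bloom] *= params.bloom_resuspension_factor

    # --- SPM: resuspension-settling balance ---------------------------------
    s = np.empty(n)
    s[0] = params.spm_background + params.resuspension_coeff * np.mean(tc**2) / params.settling_rate
    for i in range(n - 1):
        ds = a[i] * tc_del[i] ** 2 - params.settling_rate * (s[i] - params.spm_background)
        s[i + 1] = max(s[i] + dt_h * ds, 0.0)

    # --- light field ---------------------------------------------------------
    day = _daylight(times)
    season = _season(times, 0.35, 1.0, peak_doy=172.0)  # solar elevation, peak at solstice
    i0 = params.surface_par_max * season * day
    kd = params.kd_water + params.kd_per_spm * s
    par_1m = i0 * np.exp(-kd * 1.0)

    # --- pelagic growth pool -------------------------------------------------
    mu_max = params.growth_rate_max / 24.0  # h^-1
    loss = params.loss_rate / 24.0
    seed_flux = params.seed_stock / 24.0
    b = np.empty(n)
    b[0] = 0.1
    for i in range(n - 1):
        mu = mu_max * par_1m[i] / (par_1m[i] + params.light_half_saturation)
        b[i + 1] = max(b[i] + dt_h * (b[i] * (mu - loss) + seed_flux), 0.0)

    chl_true = params.chl_spm_fraction * s + b
    fluor = chl_true * (1.0 - params.quench_amplitude * day)

    # --- water-mass tracers --------------------------------------------------
    amp_ref = sum(c.amplitude for c in default_constituents())
    w_rel = (tide.values - np.nanmean(tide.values)) / amp_ref
    sal = params.salinity_mean + params.salinity_tide_amplitude * w_rel
    nit = np.clip(
        _season(times, params.nitrate_summer, params.nitrate_winter, peak_doy=45.0)
        - params.nitrate_tide_amplitude * w_rel,
        0.05,
        None,
    )
    temp = (
        _season(times, params.temp_winter, params.temp_summer, peak_doy=228.0)
        + 0.15 * w_rel  # small advective semidiurnal term; no diel heating
    )

    # --- observation noise ---------------------------------------------------
    sig, alpha = params.noise_sigma, params.noise_ar1_alpha
    if sig > 0:
        fluor = fluor * np.exp(sig * _ar1_noise(streams["chl"], n, alpha))
        s_obs = s * np.exp(sig * _ar1_noise(streams["spm"], n, alpha))
        nit = nit * np.exp(sig * _ar1_noise(streams["nit"], n, alpha))
        par_obs = par_1m * np.exp(sig * _ar1_noise(streams["par"], n, alpha))
        sal = sal + 0.05 * _ar1_noise(streams["sal"], n, alpha)
        temp = temp + 0.1 * _ar1_noise(streams["temp"], n, alpha)
    else:
        s_obs, par_obs = s, par_1m

    def mk(v, name, units):
        return TimeSeries(tide.start_time, tide.step, v, name, units)

    truth = {
        "constituent_periods_min": {c.name: c.period for c in default_constituents()},
        "entrainment_delay_min": params.entrainment_delay,
        "bloom_window": [str(b) for b in params.bloom_window] if params.bloom_window else None,
        "seed": params.seed,
        "settling_rate_per_h": params.settling_rate,
        "resuspension_coeff": params.resuspension_coeff,
        "note": "settling/resuspension rates are tuning constants, not site measurements",
    }
    return SyntheticDataset(
        water_level=tide.copy(),
        chlorophyll=mk(fluor, "chlorophyll", "mg m-3"),
        spm=mk(s_obs, "spm", "mg L-1"),
        salinity=mk(sal, "salinity", "psu"),
        temperature=mk(temp, "temperature", "degC"),
        nitrate=mk(nit, "nitrate", "mmol m-3"),
        par=mk(par_obs, "par", "umol m-2 s-1"),
        truth=truth,
    )


def inject_gaps(
    series: TimeSeries, gap_lengths: Sequence[int], seed: int
) -> TimeSeries:
    """Copy of *series* with runs of samples set to missing.

    Gap positions are drawn uniformly at random (seeded) and are mutually
    non-overlapping; the original series is untouched.
    """
    n = len(series)
    gaps = sorted((int(g) for g in gap_lengths), reverse=True)
    if any(g < 1 for g in gaps):
        raise ValueError("gap lengths must be positive")
    if any(g > n for g in gaps):
        raise ValueError("gap longer than the series")
    if sum(gaps) >= n:
        raise ValueError("total gap length must be smaller than the series")
    out = series.copy()
    occupied = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    for g in gaps:
        for _ in range(100_000):
            start = int(rng.integers(0, n - g + 1))
            if not occupied[start : start + g].any():
                occupied[start : start + g] = True
                out.values[start : start + g] = np.nan
                break
        else:
            raise RuntimeError("could not place gaps without overlap")
    return out
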