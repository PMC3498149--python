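# tidewave

Wavelet analysis of tidally forced coastal time series — with a synthetic
mooring-data generator so every stage of the analysis can be verified
against known ground truth.

## The problem

Shallow, well-mixed coastal seas with a semidiurnal tide impose a whole
hierarchy of periodicities on phytoplankton and suspended sediment:
horizontal water-mass displacement every 12 h 25 min (M2), tidal current
speed — and hence turbulent mixing and resuspension — peaking every
6 h 12 min, a ~14.8 d spring-neap cycle from M2–S2 interference, a ~27.5 d
apogee-perigee modulation from M2–N2, plus the exactly-24 h solar cycle
(daytime non-photochemical quenching of chlorophyll fluorescence).
Disentangling these overlapping rhythms in noisy, gappy mooring telemetry —
and measuring who leads whom by how much — is the job of this package. It
is aimed at biological oceanographers and monitoring programmes working
with high-frequency buoy data (chlorophyll fluorescence, SPM, salinity,
temperature, nitrate, PAR, tide-gauge water levels).

## What it computes

- **Preprocessing** — hourly/daily averaging (daily chlorophyll restricted
  to dark samples, PAR < 1 µmol quanta m⁻² s⁻¹), linear interpolation of
  single-sample gaps, and the three-step transform to relative rates of
  change: `r_t = z_t − z_{t−1}` with `z` the 3-point moving average of
  `ln x`. Gap-free segments longer than 100 h (hourly) or 60 d (daily) are
  analysed separately.
- **Tidal forcing** — daily tidal range (max − min water level) and the
  current-speed proxy `TC = |ΔW/Δt|`.
- **Morlet continuous wavelet transform** — `ψ₀(η) = π^(−1/4) e^(iω₀η)
  e^(−η²/2)` with ω₀ = 6, scales `s_j = s₀ 2^(j·dj)`, Fourier period
  `λ = 4πs/(ω₀+√(2+ω₀²))`, cone of influence at the e-folding distance
  `√2·s`. Pointwise significance against an AR(1) red-noise background
  `P_k = (1−α²)/(1+α²−2α cos 2πf)` at the χ²₂ 95 % level; global (time-
  averaged) spectra aggregate all segments with time-point weighting.
- **Wavelet coherence** — `R²(s,t) = |S(W^XY/s)|² / (S(|W^X|²/s)·S(|W^Y|²/s))`
  with Gaussian-in-time / boxcar-in-scale smoothing `S`; phase angles from
  the smoothed cross-spectrum (positive phase = first series leads);
  Monte-Carlo significance from AR(1) surrogate pairs; circular statistics
  of significant phase angles per period band.
- **Synthetic data** — harmonic tides (M2/S2/N2), SPM from a delayed
  resuspension–settling balance driven by TC², chlorophyll as a
  resuspended fraction plus a light-limited growth pool (with optional
  bloom-window "escape"), salinity/nitrate in phase/anti-phase with the
  water level, solar-locked quenching, AR(1) observation noise, gap
  injection — all reproducible from a seed, with a ground-truth sidecar.

## Worked example

```python
import tidewave as tw

# 60 days of synthetic mooring data on an M2+S2+N2 tide
tide = tw.generate_water_level(tw.TideConfig(duration=60))
data = tw.generate_ecosystem(tide, tw.EcosystemParams(seed=1))

# hourly chlorophyll -> relative rates of change
rate = tw.log_smooth_diff(tw.hourly_average(data.chlorophyll))
seg = tw.segment(rate, tw.MIN_SEGMENT_HOURLY)[0].extract(rate)

# global wavelet spectrum and its quarter-diurnal peak
spec = tw.morlet_cwt(seg)
gs = tw.global_spectrum([spec], tw.estimate_ar1(seg))
period, _ = tw.peak_period(gs, band=(300, 450))
print(f"chlorophyll-rate peak: {period/60:.2f} h")

# coherence of the chlorophyll rate with tidal current speed
tc = tw.tidal_current_speed(data.water_level, hourly=True)
x, y = tw.overlap(seg, tc)
coh = tw.wavelet_coherence(x, y)
coh = tw.mc_coherence_significance(x, y, coh, n_surrogates=300, seed=1)
hist = tw.phase_distribution(coh, band=(300, 450))
print(f"phase: {hist.circular_mean:.0f} deg "
      f"-> lag {tw.phase_to_lag(hist.circular_mean, 372.6):.0f} min")
```

prints

```
chlorophyll-rate peak: 6.20 h
phase: 315 deg -> lag 47 min
```

i.e. the chlorophyll rate of change fluctuates at the 6 h 12 min
periodicity of the tidal current speed, in phase with it up to a ~45-min
entrainment delay (resuspended material takes that long to reach the
sensor after peak currents) — which is exactly the delay the simulator
was configured with.

A command-line interface wraps the same steps
(`tidewave simulate | preprocess | tides | wavelet | coherence | run`);
`tidewave run --config cfg.yaml --out results --seed 1` executes the whole
pipeline and writes a machine-readable `summary.json`.

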