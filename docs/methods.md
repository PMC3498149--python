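# Methods

## Scope

`tidewave` couples a mechanistic simulator of tidally forced mooring data
with a wavelet analysis chain (Morlet CWT, red-noise significance, wavelet
coherence, phase statistics). The simulator exists so that every claim the
analysis makes — "this series peaks at 6 h 12 min", "these two series are
in phase up to a 45-minute lag" — can be tested against inputs whose
ground truth is known exactly. Nothing in the analysis chain depends on
the simulator.

## The simulator

### Tide

Water level is a sum of harmonic constituents,
`W(t) = W₀ + Σ Aᵢ cos(2πt/Tᵢ + φᵢ)`, sampled at a 10-min gauge cadence by
default. The default constituents are M2 (2.15 m, 745.2 min), S2 (0.65 m,
720.0 min) and N2 (0.42 m, 759.5 min). Periods are the standard
astronomical values; the M2 amplitude is set so a pure M2 tide gives a
4.3 m mean daily range, typical of an outer-estuary station in the
southern North Sea, and S2/N2 amplitudes keep realistic spring-neap
(~14.77 d) and apogee-perigee (~27.5 d) modulation of that range. No
hydrodynamics and no spatial structure are modelled: the tide is purely
kinematic forcing.

### Suspended sediment and chlorophyll

SPM obeys a forward-Euler difference equation at the tide cadence,

    S(t+Δ) = S(t) + Δ·[ a·TC(t−δ)² − λ·(S(t) − S_bg) ],

with `TC = |ΔW/Δt|` the current-speed proxy computed internally from the
tide, `a` the resuspension coefficient (3.3 mg L⁻¹ h⁻¹ per (m h⁻¹)²), `δ`
the entrainment delay (45 min — the time resuspended material takes to
reach sensor depth after peak currents), `λ` the settling rate (0.1 h⁻¹ ≈
2.4 d⁻¹, i.e. aggregate-like sinking of ~35 m d⁻¹ distributed over a 15 m
column) and `S_bg` a 5 mg L⁻¹ background of permanently suspended fines.
These rate constants are tuning constants, not site measurements, and are
flagged as such in the ground-truth sidecar. The quadratic TC forcing
makes the quarter-diurnal (6 h 12 min) line the dominant SPM periodicity
and the spring-neap cycle its low-frequency envelope. Because the analysis
convention and the simulator share the same `|ΔW/Δt|` proxy, phase
relations between simulated series and tidal forcing are exact by
construction (consistency was preferred over hydrodynamic realism).

Chlorophyll fluorescence combines a resuspended ("tychoplankton")
fraction proportional to SPM and a pelagic growth pool `B`:

    F(t) = [ f·S(t) + B(t) ] · (1 − q·daylight(t)),
    dB/dt = B·( μ_max·L/(L+K_L) − m ) + σ_seed,

with `f = 0.08 mg chl m⁻³ per mg SPM L⁻¹` (≈2 mg m⁻³ background
chlorophyll on 25 mg L⁻¹ SPM), `μ_max = 1.5 d⁻¹` (temperate diatoms),
`K_L = 100 µmol quanta m⁻² s⁻¹`, loss `m = 0.8 d⁻¹` (grazing +
respiration) and a small immigration flux `σ_seed = 0.02 mg m⁻³ d⁻¹` that
keeps the pool alive through winter. Light at 1 m depth is the clipped
solar sinusoid (period exactly 24.000 h, seasonal amplitude modulation)
attenuated by `Kd = 0.2 + 0.06·S` m⁻¹, so turbidity controls growth.
`q` is the non-photochemical quenching amplitude (default 0.3): the
daytime depression of fluorescence yield that imprints a sharp 24.0 h
line, deliberately distinct from the 24 h 50 min lunar alternative.

Inside an optional bloom window the resuspension coefficient is scaled by
0.3: SPM settles out, light improves, `B` outgrows its losses, and the
chlorophyll signal decouples ("escapes") from the spring-neap rhythm —
the behaviour the daily-scale coherence analysis is designed to detect.

### Tracers, noise, gaps

Salinity varies in phase and nitrate in anti-phase with water level
(estuarine exchange: saltier, nutrient-poorer water at high tide), on top
of seasonal baselines; temperature is a seasonal sinusoid (6.1–18.6 °C)
with a small semidiurnal advective term and deliberately no diel heating
term. Observation noise is multiplicative lognormal AR(1) (α = 0.5,
σ = 0.15) on the positive concentration variables and small additive
AR(1) noise on temperature and salinity — multiplicative red noise is the
natural choice because the analysis log-transforms the data and tests
against an AR(1) null. Every stochastic component draws from a
per-variable substream of a single seed; with noise off the simulator is
bit-reproducible. Gap injection places seeded, non-overlapping runs of
missing samples after simulation.

### What the simulator does not emulate

Wind and storm resuspension, advective patchiness, biofouling drift,
sensor recalibration steps, species succession, nutrient limitation of
the bloom (the window is prescribed, not emergent), and any spatial or
vertical structure. Passing tests therefore demonstrate that the analysis
recovers the mechanisms that are in the generator — not that real
moorings contain only those mechanisms.

## The analysis chain

### Preprocessing

Averaging bins (hour/day) with less than half their expected samples are
marked missing, so a stray sample cannot represent a bin; daily
chlorophyll instead requires at least one dark sample (strict
PAR < 1 µmol quanta m⁻² s⁻¹), because dark samples are structurally a
minority of each day. The rate transform is ln → centred 3-point mean →
first difference; smoothing windows touching a missing value propagate
missingness rather than renormalising (conservative, keeps segment logic
simple), and the rate series is one sample shorter than its source.
Only isolated single missing samples are interpolated. Segments must
exceed 100 hourly or 60 daily samples strictly, matching the ~25 %-of-
length detection limit of the wavelet analysis. Calendar days are taken
in the series' own clock (no time-zone handling).

### Morlet transform

Frequency-domain implementation: FFT of the demeaned, zero-padded segment
multiplied by `√(2πs/Δt)·π^(−1/4)·exp(−(sω−ω₀)²/2)` on positive
frequencies, inverse-transformed per scale. ω₀ = 6; scale ladder
`s_j = s₀·2^(j·dj)` with `s₀ = 2Δt`, `dj = 1/24` (1/32 where 24.0 h must
be resolved against 24.83 h — those two periods are 1.6 scale steps apart
at dj = 1/32 before refinement), reaching 25 % of the segment length.
Padding goes to the next power of two at least twice the segment length,
making the FFT a linear convolution; agreement with a literal time-domain
convolution oracle is < 10⁻⁶ relative error for scales in `[4Δt, N/8·Δt]`.
The bounds are principled: below 4Δt the sampled wavelet spectrum is
truncated at the Nyquist frequency (at s = 2Δt roughly a third of the
kernel mass lies beyond it, so expected power dips below the white-noise
level there), and above N/8 the circular wraparound of the padded FFT
becomes visible at the 10⁻⁶ level. Power is stored un-rescaled (|W|²,
expectation = series variance for white noise at every scale); the
`power/s` view exists for plotting only. The cone of influence is the
e-folding distance √2·s mapped to period units; significance masks never
extend inside it.

### Significance

Pointwise: threshold = variance × AR(1) background at the scale's Fourier
frequency × χ²₂(level)/2, with α the lag-1 sample autocorrelation of the
segment clipped to [0, 0.999] and variance computed per segment (segments
are the analysis unit). Global spectra average local power over the union
of segment time points — longer segments weigh proportionally more, which
follows directly from "average over all time points included"; the
alternative (equal weight per segment) was considered and rejected as it
makes the spectrum depend on an arbitrary segmentation of equal data.
Their significance curve uses the time-averaged χ² approximation with
`ν = 2√(1 + (nΔt/(γs))²)`, γ = 2.32 (Morlet decorrelation factor); the
reconstruction constant C_δ = 0.776 is fixed in `wavelet.py` and verified
by a 5 % energy-closure test. Peak periods are refined by a parabola
through the peak bin and its neighbours in (log₂ period, power); ties
break toward the shorter period, and a maximum on a band edge is returned
unrefined with a boundary flag.

### Coherence

`R² = |S(W^XY/s)|² / (S(|W^X|²/s)·S(|W^Y|²/s))` with smoothing S =
Gaussian in time (standard deviation equal to the scale, applied in the
frequency domain on a zero-padded copy) followed by a boxcar across
scales of 0.6 octaves — the standard constants for ω₀ = 6. Phase is the
argument of the smoothed cross-spectrum; positive phase means the first
series leads, so a series lagging by L at period P shows
`360 − 360·L/P` degrees, reported on [0°, 360°). Significance is Monte
Carlo: per-scale 95 % quantiles of R² pooled over outside-COI time points
of ≥ 100 (default 300) AR(1) surrogate pairs matched to the two series in
length and lag-1 autocorrelation, reproducible from a seed. Phase
histograms (default 20° bins — wide enough that one bin captures a
coherent phase cluster, configurable) pool all significant in-band
outside-COI cells and report the circular mean and standard deviation;
pooling across the whole band rather than a single scale row was chosen
because significant regions span adjacent scales.

### Pairing conventions

When a rate-of-change series is compared with tidal current speed, TC is
computed by differencing the *hourly-averaged* water level, so both
series are backward differences of identically binned means and their
effective timestamps coincide; differencing at the native 10-min gauge
cadence first and averaging afterwards displaces TC by ~25 min relative
to the rate series, which at the 372-min period is a spurious ~24° phase
offset. The native-cadence path remains available (`tidal_current_speed(...,
hourly=False)`, the default for spectral analysis of TC itself, where
timestamps are irrelevant).

## Problem sizes

The test-suite and acceptance computations use 30–360 day simulations at
10-min cadence, oracle comparisons at N ≤ 512, 150–200 noise replicates
for calibration checks, and 100–300 Monte-Carlo surrogates per coherence
test — sizes chosen so each check is statistically decisive while the
whole suite runs comfortably on a single CPU.

## Known limitations

- The smallest two to three scales of the ladder (s < 4Δt) carry a
  Nyquist-truncation bias; peaks there should be treated with caution.
- AR(1) is the only null model; strongly periodic "noise" (e.g. residual
  tidal lines) inflates α and makes the test conservative.
- Monte-Carlo coherence thresholds pool over time, so they are per-scale,
  not per-cell; near-COI cells inherit the scale's pooled threshold.
- The simulator's bloom is prescribed by a window, not by emergent
  nutrient dynamics; "escape" tests verify detection, not prediction.
- Missing-data handling assumes gaps are missing-at-random; biofouling
  (systematically low values before a gap) is not modelled.
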