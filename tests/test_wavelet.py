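import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

import tidewave as tw
from tidewave.wavelet import (
    C_DELTA_MORLET,
    GlobalSpectrum,
    RedNoiseModel,
    WaveletParams,
    fourier_factor,
)

from conftest import T0, make_series


def direct_convolution_cwt(x, dt, scales, omega0=6.0):
    """Independent oracle: literal time-domain correlation with the sampled,
    scaled, conjugated mother wavelet (signal treated as zero outside)."""
    x = x - x.mean()
    n = len(x)
    idx = np.arange(n)
    out = np.empty((len(scales), n), dtype=complex)
    for j, s in enumerate(scales):
        eta = (idx[None, :] - idx[:, None]) * dt / s
        psi = np.pi**-0.25 * np.exp(1j * omega0 * eta) * np.exp(-(eta**2) / 2)
        out[j] = (x[None, :] * np.conj(psi)).sum(axis=1) * np.sqrt(dt / s)
    return out


class TestMorletCwt:
    def test_fft_matches_direct_convolution(self):
        # Restricted to scales where the sampled wavelet is not aliased
        # (s >= 4*dt) and zero-padding wraparound is negligible (s <= N/8).
        n = 256
        x = np.random.default_rng(0).standard_normal(n)
        sp = tw.morlet_cwt(make_series(x, step=1.0))
        keep = (sp.scales >= 4.0) & (sp.scales <= n / 8)
        oracle = direct_convolution_cwt(x, 1.0, sp.scales[keep])
        for row, orc in zip(sp.coefficients[keep], oracle):
            rel = np.abs(row - orc).max() / np.abs(orc).max()
            assert rel < 1e-6

    def test_sinusoid_peaks_at_its_period(self):
        P = 32.0
        t = np.arange(256)
        x = np.sin(2 * np.pi * t / P)
        ts = make_series(x, step=1.0)
        sp = tw.morlet_cwt(ts)
        gs = tw.global_spectrum([sp], RedNoiseModel(0.0, x.var()))
        period, boundary = tw.peak_period(gs)
        assert not boundary
        assert abs(period - P) / P < 0.05
        # interior local maxima align with the same scale band
        j = np.argmin(np.abs(sp.fourier_periods - P))
        mid = sp.power[:, 100:150]
        assert np.all(np.abs(np.argmax(mid, axis=0) - j) <= 1)

    def test_power_scales_quadratically_with_amplitude(self):
        t = np.arange(128)
        x = np.sin(2 * np.pi * t / 16)
        a = tw.morlet_cwt(make_series(x, step=1.0))
        b = tw.morlet_cwt(make_series(2 * x, step=1.0))
        np.testing.assert_allclose(b.power, 4 * a.power, rtol=1e-9)

    def test_white_noise_mean_power_is_flat(self):
        # E|W|^2 = sigma^2 at every scale in the un-rescaled convention;
        # checked well inside the series (twice the COI distance from edges).
        n = 256
        acc = None
        reps = 150
        for k in range(reps):
            x = np.random.default_rng(1000 + k).standard_normal(n)
            sp = tw.morlet_cwt(make_series(x, step=1.0))
            dist = np.minimum(np.arange(n), np.arange(n)[::-1])[None, :]
            interior = dist >= 2 * np.sqrt(2.0) * sp.scales[:, None]
            pw = np.where(interior, sp.power, np.nan)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows at large scales
                m = np.nanmean(pw, axis=1)
            acc = m if acc is None else acc + m
        mean_power = acc / reps
        # scales below ~4*dt lose power to Nyquist truncation (as in the
        # oracle comparison); the flatness property applies above that.
        keep = ~np.isnan(mean_power) & (sp.scales >= 4.0)
        assert keep.sum() > 20
        np.testing.assert_allclose(mean_power[keep], 1.0, atol=0.12)

    def test_energy_reconstruction_within_five_percent(self):
        t = np.arange(512)
        x = np.sin(2 * np.pi * t / 16) + 0.5 * np.sin(2 * np.pi * t / 40 + 1.0)
        sp = tw.morlet_cwt(make_series(x, step=1.0), WaveletParams(dj=1 / 24))
        recon = (
            sp.params.dj / (C_DELTA_MORLET * len(t)) * (sp.power / sp.scales[:, None]).sum()
        )
        assert abs(recon - x.var()) / x.var() < 0.05

    def test_coi_linear_from_edges_and_symmetric(self):
        sp = tw.morlet_cwt(make_series(np.random.default_rng(2).standard_normal(100), step=5.0))
        np.testing.assert_allclose(sp.coi, sp.coi[::-1])
        first_half = sp.coi[1:50]
        d = np.diff(first_half)
        np.testing.assert_allclose(d, d[0])  # linear growth
        assert sp.coi.max() <= fourier_factor() / np.sqrt(2) * 5.0 * 50

    def test_detection_limit_quarter_of_segment(self):
        n = 400
        t = np.arange(n)
        # recoverable: period at ~22% of the length
        x = np.sin(2 * np.pi * t / 90)
        sp = tw.morlet_cwt(make_series(x, step=1.0))
        gs = tw.global_spectrum([sp], RedNoiseModel(0.0, x.var()))
        period, _ = tw.peak_period(gs, (60, 120))
        assert abs(period - 90) / 90 < 0.05
        # beyond the limit: every cell of the 150-sample band sits in the COI
        params = WaveletParams(n_scales=160)
        sp2 = tw.morlet_cwt(make_series(x, step=1.0), params)
        j = np.argmin(np.abs(sp2.fourier_periods - 150))
        assert sp2.fourier_periods[j] > 140
        assert not sp2.outside_coi()[j].any()

    def test_missing_values_rejected(self):
        v = np.ones(50)
        v[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            tw.morlet_cwt(make_series(v))


class TestAr1:
    def test_white_noise_alpha_near_zero(self):
        n = 10_000
        x = np.random.default_rng(3).standard_normal(n)
        m = tw.estimate_ar1(make_series(x))
        assert abs(m.alpha) < 3 / np.sqrt(n)

    def test_recovers_known_alpha(self):
        alpha = 0.72
        eps = np.random.default_rng(4).standard_normal(10_000) * np.sqrt(1 - alpha**2)
        x = lfilter([1.0], [1.0, -alpha], eps)
        m = tw.estimate_ar1(make_series(x))
        assert 0.69 <= m.alpha <= 0.75

    def test_white_background_is_flat(self):
        m = RedNoiseModel(alpha=0.0, variance=1.0)
        freq = np.linspace(0.01, 0.5, 20)
        np.testing.assert_allclose(m.background(freq), 1.0)

    def test_red_background_concentrates_at_low_frequency(self):
        m = RedNoiseModel(alpha=0.7, variance=1.0)
        assert m.background(np.array([0.01]))[0] > 1.0 > m.background(np.array([0.45]))[0]

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            tw.estimate_ar1(make_series(np.full(10, 2.0)))


class TestSignificance:
    def test_white_noise_false_positive_rate(self):
        fracs = []
        for k in range(60):
            x = np.random.default_rng(500 + k).standard_normal(256)
            ts = make_series(x)
            sp = tw.rednoise_significance(tw.morlet_cwt(ts), tw.estimate_ar1(ts))
            out = sp.outside_coi()
            fracs.append(sp.signif_mask[out].sum() / out.sum())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_level_near_one_empties_the_mask(self):
        x = np.random.default_rng(6).standard_normal(256)
        ts = make_series(x)
        sp = tw.rednoise_significance(tw.morlet_cwt(ts), tw.estimate_ar1(ts), level=1 - 1e-12)
        assert not sp.signif_mask.any()

    def test_strong_sinusoid_band_is_significant(self):
        t = np.arange(300)
        x = np.sin(2 * np.pi * t / 24) + 0.1 * np.random.default_rng(7).standard_normal(300)
        ts = make_series(x)
        sp = tw.rednoise_significance(tw.morlet_cwt(ts), tw.estimate_ar1(ts))
        j = np.argmin(np.abs(sp.fourier_periods - 24 * 60.0))  # 24 samples of 60 min
        out = sp.outside_coi()[j]
        assert sp.signif_mask[j, out].mean() > 0.95
        # the mask never extends into the cone of influence
        assert not (sp.signif_mask & ~sp.outside_coi()).any()


class TestGlobalSpectrum:
    def test_single_segment_is_time_mean(self):
        x = np.random.default_rng(8).standard_normal(200)
        sp = tw.morlet_cwt(make_series(x))
        gs = tw.global_spectrum([sp], RedNoiseModel(0.0, x.var()))
        np.testing.assert_allclose(gs.mean_power, sp.power.mean(axis=1))

    def test_duplicate_segment_leaves_mean_unchanged(self):
        x = np.random.default_rng(9).standard_normal(200)
        sp = tw.morlet_cwt(make_series(x))
        g1 = tw.global_spectrum([sp], RedNoiseModel(0.0, x.var()))
        g2 = tw.global_spectrum([sp, sp], RedNoiseModel(0.0, x.var()))
        np.testing.assert_allclose(g1.mean_power, g2.mean_power)
        assert g2.n_timepoints == 2 * g1.n_timepoints

    def test_time_point_weighting_matches_concatenated_average(self):
        rng = np.random.default_rng(10)
        params = WaveletParams(n_scales=60)
        a = tw.morlet_cwt(make_series(rng.standard_normal(100)), params)
        b = tw.morlet_cwt(make_series(rng.standard_normal(300)), params)
        gs = tw.global_spectrum([a, b], RedNoiseModel(0.0, 1.0))
        oracle = (a.power.sum(axis=1) + b.power.sum(axis=1)) / 400.0
        np.testing.assert_allclose(gs.mean_power, oracle)

    def test_mismatched_scale_grids_rejected(self):
        a = tw.morlet_cwt(make_series(np.random.default_rng(11).standard_normal(100)),
                          WaveletParams(n_scales=40))
        b = tw.morlet_cwt(make_series(np.random.default_rng(12).standard_normal(100)),
                          WaveletParams(n_scales=50))
        with pytest.raises(ValueError, match="scale grid"):
            tw.global_spectrum([a, b], RedNoiseModel(0.0, 1.0))


class TestPeakPeriod:
    def test_symmetric_peak_returns_bin_exactly(self):
        periods = 745.0 * 2.0 ** (np.arange(-5, 6) / 24.0)
        power = np.exp(-0.5 * (np.arange(-5, 6) ** 2))  # symmetric in log-period
        gs = GlobalSpectrum(periods, power, np.zeros_like(power), 100)
        period, boundary = tw.peak_period(gs)
        assert not boundary
        assert period == pytest.approx(745.0, rel=1e-12)

    def test_monotone_band_flags_boundary(self):
        periods = 2.0 ** np.arange(1, 11)
        power = np.arange(10, dtype=float)
        gs = GlobalSpectrum(periods, power, np.zeros_like(power), 100)
        period, boundary = tw.peak_period(gs, (4.0, 256.0))
        assert boundary
        assert period == 256.0

    def test_tie_breaks_toward_shorter_period(self):
        periods = 2.0 ** np.arange(8)
        power = np.array([0.0, 1.0, 5.0, 1.0, 1.0, 5.0, 1.0, 0.0])
        gs = GlobalSpectrum(periods, power, np.zeros_like(power), 100)
        period, _ = tw.peak_period(gs)
        assert period == pytest.approx(4.0)

    def test_empty_band_rejected(self):
        gs = GlobalSpectrum(np.array([10.0, 20.0]), np.array([1.0, 2.0]), np.zeros(2), 10)
        with pytest.raises(ValueError):
            tw.peak_period(gs, (30.0, 40.0))
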