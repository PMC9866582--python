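"""Tests for the wavelet/sliding-window denoising chain."""

import math

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from pulsekit.denoise import (compute_threshold, denoise_pipeline, dwt5,
                              idwt5, remove_baseline, remove_phase_offset,
                              segment_periods, shrink_coeffs, stft)
from pulsekit.synth import NoiseSpec, ZERO_NOISE, synthesize_record
from pulsekit.waveform import SignalTrace

FS = 125.0


class TestStft:
    def test_zero_signal_all_zero(self):
        spec = stft(SignalTrace(np.zeros(500), fs=FS), 125, 62)
        assert np.all(spec.magnitudes == 0.0)

    def test_tone_peaks_at_matching_bin(self):
        t = np.arange(500) / FS
        spec = stft(SignalTrace(np.sin(2 * np.pi * 5.0 * t), fs=FS), 125, 125)
        assert np.all(np.argmax(spec.magnitudes, axis=0) == 5)
        assert spec.freqs[5] == pytest.approx(5.0)

    def test_parseval_per_frame_rectangular_window(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=375)
        n = 125
        spec = stft(SignalTrace(x, fs=FS), n, n)
        w = np.full(n // 2 + 1, 2.0)
        w[0] = 1.0  # DC bin is unpaired (and Nyquist, when n is even)
        if n % 2 == 0:
            w[-1] = 1.0
        for k, s in enumerate(range(0, 375 - n + 1, n)):
            e_time = np.sum(x[s:s + n] ** 2)
            e_freq = np.sum(w * spec.magnitudes[:, k] ** 2) / n
            assert e_freq == pytest.approx(e_time, rel=1e-6)


class TestDwt:
    def test_constant_signal_lives_in_scaling_band(self):
        d = dwt5(SignalTrace(np.full(512, 3.0), fs=FS))
        total = sum(np.sum(c**2) for c in d.coeff_list())
        detail = sum(np.sum(c**2) for c in d.cd)
        assert detail < 1e-10 * total

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_on_random_signals(self, seed):
        x = np.random.default_rng(seed).normal(size=500)
        tr = SignalTrace(x, fs=FS)
        out = idwt5(dwt5(tr), fs=FS)
        err = np.linalg.norm(out.samples - x) / np.linalg.norm(x)
        assert err <= 1e-8

    def test_parseval_with_orthogonal_wavelet_periodization(self):
        x = np.random.default_rng(1).normal(size=512)
        d = dwt5(SignalTrace(x, fs=FS))
        e_coeff = sum(np.sum(c**2) for c in d.coeff_list())
        assert e_coeff == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 32"):
            dwt5(SignalTrace(np.ones(16), fs=FS))


class TestThreshold:
    def test_zero_median_gives_zero_threshold(self):
        assert compute_threshold(np.zeros(64)).N == 0.0

    def test_unit_median_closed_form(self):
        cfg = compute_threshold(np.ones(64))
        assert cfg.N == pytest.approx(1.43 * math.sqrt(2 * math.log(500)),
                                      rel=1e-12)

    def test_homogeneity(self):
        cd1 = np.random.default_rng(2).normal(size=128)
        assert compute_threshold(2 * cd1).N == pytest.approx(
            2 * compute_threshold(cd1).N)


class TestShrinkage:
    def _decomp(self, seed=3):
        x = np.random.default_rng(seed).normal(size=512)
        return dwt5(SignalTrace(x, fs=FS))

    def test_below_threshold_zeroed_above_shrunk(self):
        from pulsekit.denoise import ThresholdConfig, WaveletDecomposition

        d = WaveletDecomposition(ca5=np.zeros(4),
                                 cd=[np.array([0.5, -2.0]) for _ in range(5)],
                                 wavelet="db4", mode="periodization", n_orig=128)
        out = shrink_coeffs(d, ThresholdConfig(N=1.0, lambda_frac=0.5))
        for cd in out.cd:
            np.testing.assert_allclose(cd, [0.0, -1.5])

    @pytest.mark.parametrize("alpha,mode", [(0.0, "hard"), (1.0, "soft")])
    def test_limits_match_reference_thresholding(self, alpha, mode):
        d = self._decomp()
        cfg = compute_threshold(d.cd1, lambda_frac=alpha)
        out = shrink_coeffs(d, cfg)
        for ours, orig in zip(out.cd, d.cd):
            ref = pywt.threshold(orig, cfg.N, mode=mode)
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(st.integers(min_value=0, max_value=1000),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_energy_never_increases(self, seed, alpha):
        d = self._decomp(seed)
        out = shrink_coeffs(d, compute_threshold(d.cd1, lambda_frac=alpha))
        for ours, orig in zip(out.cd, d.cd):
            assert np.all(np.abs(ours) <= np.abs(orig) + 1e-15)
        np.testing.assert_array_equal(out.ca5, d.ca5)


class TestSegmentation:
    def test_five_clean_cycles_found(self):
        tr, truth = synthesize_record("normal", 5, noise=ZERO_NOISE, seed=4)
        seg = segment_periods(tr)
        assert seg.n_cycles == 5
        true_lengths = np.diff(truth.boundaries)
        np.testing.assert_allclose(seg.period, true_lengths, atol=2)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="no cycles"):
            segment_periods(SignalTrace(np.full(500, 2.0), fs=FS))

    @pytest.mark.parametrize("seed", range(20))
    def test_period_estimates_within_2pct(self, seed):
        tr, truth = synthesize_record("normal", 8, noise=ZERO_NOISE, seed=seed)
        seg = segment_periods(tr)
        true_T = np.diff(truth.boundaries)
        # interior cycles are unaffected by edge handling
        assert seg.n_cycles == 8
        rel = np.abs(seg.period - true_T) / true_T
        assert np.all(rel <= 0.02)


class TestShearAndBaseline:
    def test_pure_ramp_becomes_constant(self):
        out, theta = remove_phase_offset(0.01 * np.arange(100))
        np.testing.assert_allclose(out, out[0], atol=1e-12)
        assert theta == pytest.approx(math.atan(0.01))

    def test_matched_endpoints_unchanged(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 100))
        out, theta = remove_phase_offset(x)
        assert theta == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_sine_plus_ramp_recovered(self):
        n = np.arange(200)
        sine = np.sin(2 * np.pi * n / 199)  # equal endpoints
        out, _ = remove_phase_offset(sine + 0.02 * n)
        np.testing.assert_allclose(out, sine, atol=1e-9)

    def test_endpoints_match_after_shear(self):
        x = np.random.default_rng(5).normal(size=150).cumsum()
        out, _ = remove_phase_offset(x)
        assert out[0] == pytest.approx(out[-1], abs=1e-9 * max(1, np.ptp(x)))

    def test_baseline_removal_min_zero_and_idempotent(self):
        x = np.random.default_rng(6).normal(size=80) + 5.0
        out = remove_baseline(x)
        assert out.min() == 0.0
        np.testing.assert_array_equal(remove_baseline(out), out)
        np.testing.assert_allclose(np.diff(out), np.diff(x), atol=1e-12)


class TestPipeline:
    def test_near_identity_on_clean_record(self):
        tr, truth = synthesize_record("normal", 10, noise=ZERO_NOISE, seed=7)
        clean, seg = denoise_pipeline(tr)
        ref = tr.samples[seg.offset:seg.offset + len(clean)]
        rmse = np.sqrt(np.mean((clean.samples - ref) ** 2))
        assert rmse <= 0.02 * truth.params[0].Ym

    def test_every_cycle_baselined_with_matched_endpoints(self):
        ns = NoiseSpec(baseline_amp=3.0, white_sd=0.5)
        tr, _ = synthesize_record("normal", 8, noise=ns, seed=8)
        clean, seg = denoise_pipeline(tr)
        for i in range(seg.n_cycles):
            cyc = seg.cycle(clean.samples, i)
            assert cyc.min() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_noise_rmse_reduced_by_half(self, seed):
        ns = NoiseSpec(baseline_amp=3.0, baseline_freq=0.2, white_sd=0.5)
        tr, truth = synthesize_record("normal", 10, noise=ns, seed=50 + seed)
        den, seg = denoise_pipeline(tr)
        sl = slice(seg.offset, seg.offset + len(den))
        gt = truth.clean.samples[sl]
        rmse_in = np.sqrt(np.mean((tr.samples[sl] - gt) ** 2))
        rmse_out = np.sqrt(np.mean((den.samples - gt) ** 2))
        assert rmse_out <= 0.5 * rmse_in
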