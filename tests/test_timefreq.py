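"""Morlet engine: cycle schedule, kernel spectra, convolution, dB normalization."""

import numpy as np
import pytest

from ergop.errors import ParameterError
from ergop.simulate import OpBurst, make_op_burst
from ergop.timefreq import (Scalogram, WaveletSpec, cwt_power, cycles_for_freqs,
                            group_mean_scalogram, morlet_kernel, subject_scalogram,
                            to_decibel)
from ergop.trace_io import ERGTrace, time_grid


def noise_trace(fs=5000.0, sd=10.0, seed=0, condition="DA3"):
    t = time_grid(fs)
    return ERGTrace(t, np.random.default_rng(seed).normal(0, sd, t.size), fs, condition)


class TestCycleSchedule:
    def test_endpoints(self):
        assert cycles_for_freqs([10.0])[0] == pytest.approx(3.0)
        assert cycles_for_freqs([300.0])[0] == pytest.approx(7.0)

    def test_geometric_midpoint(self):
        f_mid = np.sqrt(10.0 * 300.0)
        assert cycles_for_freqs([f_mid])[0] == pytest.approx(np.sqrt(21.0), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            cycles_for_freqs([5.0])
        with pytest.raises(ParameterError):
            cycles_for_freqs([400.0])

    def test_monotone_and_sigma_relation_exact(self):
        spec = WaveletSpec.default(5000.0)
        assert np.all(np.diff(spec.n_cycles) > 0)
        np.testing.assert_array_equal(
            spec.sigma_s, spec.n_cycles / (2 * np.pi * spec.freqs_hz))
        assert spec.freqs_hz.size == 146


class TestKernel:
    def test_center_value_before_normalization(self):
        w = morlet_kernel(40.0, 5.0, 5000.0, normalize=False)
        assert w[w.size // 2] == pytest.approx(1.0 + 0.0j)

    def test_envelope_symmetric(self):
        w = morlet_kernel(40.0, 5.0, 5000.0)
        np.testing.assert_allclose(np.abs(w), np.abs(w[::-1]), rtol=1e-12)

    def test_unit_gain_at_center_frequency(self):
        fs, f = 5000.0, 150.0
        w = morlet_kernel(f, 6.0, fs)
        t = (np.arange(w.size) - w.size // 2) / fs
        gain = np.sum(w * np.exp(-2j * np.pi * f * t)) / fs
        assert abs(gain) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("f,n", [(20.0, 3.5), (150.0, 6.0)])
    def test_spectral_peak_and_width(self, f, n):
        """Kernel spectrum peaks at f with Gaussian SD sigma_f = f/n within 5%."""
        fs = 5000.0
        w = morlet_kernel(f, n, fs)
        n_fft = 1 << 18
        spec = np.abs(np.fft.fft(w, n_fft)) ** 2
        freqs = np.fft.fftfreq(n_fft, 1 / fs)
        pos = freqs > 0
        spec, freqs = spec[pos], freqs[pos]
        peak = freqs[np.argmax(spec)]
        mean = np.sum(freqs * spec) / np.sum(spec)
        sd = np.sqrt(np.sum((freqs - mean) ** 2 * spec) / np.sum(spec))
        assert peak == pytest.approx(f, abs=freqs[0] + fs / n_fft)
        # power spectrum of a Gabor atom is Gaussian with SD sigma_f/sqrt(2)
        assert sd * np.sqrt(2) == pytest.approx(f / n, rel=0.05)

    def test_resolution_tradeoff_monotone(self):
        """Temporal spread of the power response falls with f; spectral SD rises."""
        fs = 5000.0
        t = time_grid(fs)
        impulse = np.zeros(t.size)
        impulse[np.argmin(np.abs(t - 75.0))] = 1.0
        tr = ERGTrace(t, impulse, fs, "DA3")
        spec = WaveletSpec.default(fs, f_min=20, f_max=280, f_step=65.0)
        power, _ = cwt_power(tr, spec)
        t_sds = []
        for k in range(spec.freqs_hz.size):
            p = power[:, k]
            mu = np.sum(t * p) / np.sum(p)
            t_sds.append(np.sqrt(np.sum((t - mu) ** 2 * p) / np.sum(p)))
        assert np.all(np.diff(t_sds) < 0)
        assert np.all(np.diff(spec.freqs_hz / spec.n_cycles) > 0)


class TestCwt:
    def test_pure_tone_localizes_to_nearest_grid_frequency(self):
        fs = 5000.0
        t = time_grid(fs)
        tr = ERGTrace(t, 10 * np.cos(2 * np.pi * 150.0 * t / 1000.0), fs, "DA3")
        spec = WaveletSpec.default(fs)
        power, valid = cwt_power(tr, spec)
        mean_power = np.array([power[valid[:, k], k].mean() for k in range(spec.freqs_hz.size)])
        assert spec.freqs_hz[np.argmax(mean_power)] == 150.0

    def test_zero_trace_zero_power(self):
        t = time_grid(1000.0)
        tr = ERGTrace(t, np.zeros(t.size), 1000.0, "DA10")
        power, _ = cwt_power(tr, WaveletSpec.default(1000.0, f_step=50.0))
        assert np.max(power) == 0.0

    def test_fft_convolution_matches_direct(self):
        """Frequency-domain convolution equals brute-force time-domain convolution."""
        tr = noise_trace(fs=1000.0, sd=5.0, seed=4, condition="DA10")
        spec = WaveletSpec.default(1000.0, f_min=20, f_max=160, f_step=70.0)
        power, _ = cwt_power(tr, spec)
        for k, (f, n) in enumerate(zip(spec.freqs_hz, spec.n_cycles)):
            kernel = morlet_kernel(f, n, 1000.0, spec.support_sd)
            direct = np.convolve(tr.amplitude_uV.astype(complex), kernel, mode="same")
            np.testing.assert_allclose(power[:, k], np.abs(direct) ** 2,
                                       rtol=1e-9, atol=1e-9 * np.max(power[:, k]))

    def test_short_epoch_rejected(self):
        t = time_grid(1000.0, -20.0, 100.0)
        tr = ERGTrace(t, np.zeros(t.size), 1000.0, "DA10")
        with pytest.raises(ParameterError, match="span"):
            cwt_power(tr, WaveletSpec.default(1000.0, f_step=50.0))

    def test_overlong_kernel_rejected(self):
        tr = noise_trace(fs=1000.0, condition="DA10")
        spec = WaveletSpec(np.array([10.0]), np.array([150.0]),
                           np.array([150.0]) / (2 * np.pi * 10.0), 1000.0)
        with pytest.raises(ParameterError, match="10x"):
            cwt_power(tr, spec)


class TestDecibel:
    def test_stationary_noise_near_zero_db(self):
        scal = subject_scalogram(noise_trace(seed=0), WaveletSpec.default(5000.0, f_step=10.0))
        post = scal.time_ms > 0
        vals = scal.power_db[post][scal.valid_mask[post]]
        assert -1.0 < vals.mean() < 1.0

    def test_flat_power_gives_zero_db(self):
        t = time_grid(1000.0)
        freqs = np.array([50.0, 100.0])
        power = np.ones((t.size, 2))
        scal = to_decibel(power, t, freqs, np.ones_like(power, dtype=bool))
        assert np.max(np.abs(scal.power_db)) == 0.0

    def test_gain_invariance(self):
        """Doubling the trace leaves the dB map unchanged (ratio cancels)."""
        tr = noise_trace(seed=5)
        spec = WaveletSpec.default(5000.0, f_step=50.0)
        a = subject_scalogram(tr, spec)
        b = subject_scalogram(tr.with_amplitude(2.0 * tr.amplitude_uV), spec)
        np.testing.assert_allclose(a.power_db, b.power_db, atol=1e-9)

    def test_post_stimulus_baseline_rejected(self):
        t = time_grid(1000.0)
        with pytest.raises(ParameterError):
            to_decibel(np.ones((t.size, 1)), t, np.array([50.0]),
                       np.ones((t.size, 1), dtype=bool), baseline_window=(0.0, 20.0))

    def test_injected_burst_localized(self):
        """A Gabor atom at (28 ms, 160 Hz) peaks within +-3 ms / +-10 Hz in dB."""
        fs = 5000.0
        t = time_grid(fs)
        burst = make_op_burst(OpBurst(160.0, 28.0, 15.0, 6.0), t)
        noise = np.random.default_rng(12).normal(0, 0.5, t.size)
        tr = ERGTrace(t, burst + noise, fs, "DA3")
        scal = subject_scalogram(tr)
        db = np.where(scal.valid_mask, scal.power_db, -np.inf)
        it, jf = np.unravel_index(np.argmax(db), db.shape)
        assert abs(scal.time_ms[it] - 28.0) <= 3.0
        assert abs(scal.freqs_hz[jf] - 160.0) <= 10.0


class TestGroupMean:
    def test_identical_inputs_unchanged(self):
        scal = subject_scalogram(noise_trace(seed=1), WaveletSpec.default(5000.0, f_step=50.0))
        mean = group_mean_scalogram([scal, scal])
        np.testing.assert_array_equal(mean.power_db, scal.power_db)

    def test_opposite_maps_cancel(self):
        scal = subject_scalogram(noise_trace(seed=2), WaveletSpec.default(5000.0, f_step=50.0))
        flipped = Scalogram(-scal.power_db, scal.time_ms, scal.freqs_hz,
                            scal.baseline_window_ms, scal.valid_mask)
        assert np.max(np.abs(group_mean_scalogram([scal, flipped]).power_db)) == 0.0

    def test_mean_sd_shrinks_as_sqrt_n(self):
        """SD of the n-subject mean map scales like subject SD / sqrt(n)."""
        fs, n, reps = 1000.0, 4, 30
        spec = WaveletSpec.default(fs, f_min=30, f_max=230, f_step=100.0)
        seeds = iter(range(10_000))
        def mean_map():
            scals = [subject_scalogram(noise_trace(fs, seed=next(seeds), condition="DA10"), spec)
                     for _ in range(n)]
            return group_mean_scalogram(scals)
        maps = [mean_map() for _ in range(reps)]
        singles = [subject_scalogram(noise_trace(fs, seed=next(seeds), condition="DA10"), spec)
                   for _ in range(reps)]
        mask = maps[0].valid_mask & (maps[0].time_ms > 0)[:, None]
        sd_mean = np.std([m.power_db for m in maps], axis=0)[mask].mean()
        sd_single = np.std([s.power_db for s in singles], axis=0)[mask].mean()
        assert sd_mean == pytest.approx(sd_single / np.sqrt(n), rel=0.25)

    def test_axis_mismatch_rejected(self):
        a = subject_scalogram(noise_trace(seed=3), WaveletSpec.default(5000.0, f_step=50.0))
        b = subject_scalogram(noise_trace(seed=3), WaveletSpec.default(5000.0, f_step=25.0))
        with pytest.raises(ParameterError):
            group_mean_scalogram([a, b])
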