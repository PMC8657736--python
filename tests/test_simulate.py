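"""Generator: component shapes, lobe calibration, cohort structure, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from ergop.errors import CalibrationError, ParameterError
from ergop.features import extract_wave_features, subband_trace
from ergop.simulate import (CohortConfig, OpBurst, WaveformParams, composite_trace,
                            draw_subject_params, generate_cohort, generate_trace,
                            make_component_awave, make_op_burst, preset, simulate_cohort)
from ergop.trace_io import read_manifest, read_trace, time_grid

DENSE = np.arange(-5.0, 150.0, 0.005)


class TestComponents:
    def test_awave_minimum_matches_brute_force(self, nf_presets):
        """Component minimum sits exactly at (a_amp, a_time) on a dense grid."""
        p = nf_presets["control_DA3"]
        y = make_component_awave(p, DENSE)
        i = np.argmin(y)
        assert y[i] == pytest.approx(p.a_amp_uV, abs=1e-6)
        assert DENSE[i] == pytest.approx(p.a_time_ms, abs=0.01)
        assert np.all(y[DENSE <= 0] == 0)

    def test_awave_zero_amplitude_limit(self, nf_presets):
        p = replace(nf_presets["control_DA3"], a_amp_uV=-1e-12)
        assert np.max(np.abs(make_component_awave(p, DENSE))) < 1e-11

    def test_op_burst_zero_amp(self):
        burst = OpBurst(160.0, 28.0, 0.0, 6.0)
        assert not np.any(make_op_burst(burst, DENSE))

    def test_op_burst_fft_peak_at_center_freq(self):
        """FFT magnitude of an isolated burst peaks at center_freq within one bin."""
        fs = 5000.0
        t = time_grid(fs, 0.0, 200.0)
        burst = OpBurst(160.0, 100.0, 10.0, 6.0)  # centered, far from edges
        y = make_op_burst(burst, t)
        spec = np.abs(np.fft.rfft(y, n=8 * t.size))
        freqs = np.fft.rfftfreq(8 * t.size, 1.0 / fs)
        assert abs(freqs[np.argmax(spec)] - burst.center_freq_hz) <= freqs[1] + 1e-9

    def test_op_burst_energy_closed_form(self):
        """Burst energy equals the analytic Gabor energy within 1%."""
        fs = 5000.0
        t = time_grid(fs, 0.0, 200.0)
        burst = OpBurst(160.0, 100.0, 10.0, 6.0)
        y = make_op_burst(burst, t)
        energy = np.sum(y**2) / fs
        sigma_s = burst.sigma_ms / 1000.0
        expected = burst.amp_uV**2 * sigma_s * np.sqrt(np.pi) / 2.0
        assert energy == pytest.approx(expected, rel=0.01)


class TestCalibration:
    @pytest.mark.parametrize("name", ["control_DA3", "achm_DA3", "control_DA10", "achm_DA10"])
    def test_composite_hits_trough_and_peak_targets(self, nf_presets, name):
        """Dense-grid trough/trough-to-peak of the composite match the presets."""
        p = nf_presets[name]
        y = composite_trace(p, DENSE)
        sel = (DENSE > 3) & (DENSE <= 35)
        trough = np.min(y[sel])
        peak = np.max(y[DENSE > DENSE[sel][np.argmin(y[sel])]])
        assert trough == pytest.approx(p.a_amp_uV, abs=0.01)
        assert peak - trough == pytest.approx(p.b_amp_uV, abs=0.01)

    def test_equal_amplitudes_return_to_baseline(self):
        """b_amp == |a_amp| puts the composite peak exactly at baseline 0."""
        p = WaveformParams(-100.0, 14.0, 100.0, 45.0,
                           OpBurst(85.0, 20.0, 0.0, 8.0), OpBurst(160.0, 28.0, 0.0, 6.0),
                           noise_sd_uV=0.0, drift_sd_uV=0.0)
        y = composite_trace(p, DENSE)
        sel = (DENSE > 3) & (DENSE <= 35)
        trough = np.min(y[sel])
        peak = np.max(y[DENSE > DENSE[sel][np.argmin(y[sel])]])
        assert trough == pytest.approx(-100.0, abs=0.01)
        assert abs(peak) < 0.01

    def test_infeasible_targets_raise(self):
        bursts = OpBurst(85.0, 20.0, 0.0, 8.0), OpBurst(160.0, 28.0, 0.0, 6.0)
        p = WaveformParams(-50.0, 15.0, 1.0, 45.0, *bursts,
                           noise_sd_uV=0.0, drift_sd_uV=0.0)
        with pytest.raises(CalibrationError):
            composite_trace(p, DENSE)


class TestGenerateTrace:
    def test_noise_free_equals_composite(self, nf_presets):
        p = nf_presets["control_DA10"]
        tr = generate_trace(p, 1000.0, "DA10", seed=3)
        np.testing.assert_allclose(tr.amplitude_uV, composite_trace(p, tr.time_ms))

    def test_same_seed_identical(self):
        p = preset("control", "DA10")
        a = generate_trace(p, 1000.0, "DA10", seed=11)
        b = generate_trace(p, 1000.0, "DA10", seed=11)
        np.testing.assert_array_equal(a.amplitude_uV, b.amplitude_uV)

    def test_noise_variance_additivity(self, nf_presets):
        """Trace minus composite has the configured noise variance within 10%."""
        p = replace(nf_presets["control_DA3"], noise_sd_uV=10.0)
        resid = []
        for seed in range(10):
            tr = generate_trace(p, 5000.0, "DA3", seed=seed)
            resid.append(tr.amplitude_uV - composite_trace(p, tr.time_ms))
        resid = np.concatenate(resid)
        assert resid.size >= 10_000
        assert np.var(resid) == pytest.approx(100.0, rel=0.10)

    def test_feature_recovery_end_to_end(self, nf_presets):
        p = nf_presets["control_DA3"]
        feats = extract_wave_features(generate_trace(p, 5000.0, "DA3"))
        assert feats.a_amp_uV == pytest.approx(p.a_amp_uV, abs=1.0)


class TestCohort:
    def test_counts(self, tmp_path):
        config = CohortConfig(2, 2, "DA10", 1000.0, preset("control", "DA10"),
                              preset("achm", "DA10"), between_subject_cv=0.1, seed=5)
        manifest = generate_cohort(config, str(tmp_path))
        assert len(manifest.table) == 40
        assert len(list((tmp_path / "traces").glob("*.tsv"))) == 40
        assert (tmp_path / "simulation.json").exists()

    def test_cohort_regeneration_byte_identical(self, cohort_dir, tmp_path):
        out, _, config = cohort_dir
        generate_cohort(config, str(tmp_path))
        for f in sorted((out / "traces").glob("*.tsv")):
            assert f.read_bytes() == (tmp_path / "traces" / f.name).read_bytes()
        assert (out / "manifest.tsv").read_bytes() == (tmp_path / "manifest.tsv").read_bytes()

    def test_zero_cv_zero_noise_subjects_identical(self):
        base = replace(preset("control", "DA10"), noise_sd_uV=0.0, drift_sd_uV=0.0)
        config = CohortConfig(2, 2, "DA10", 1000.0, base,
                              replace(preset("achm", "DA10"), noise_sd_uV=0.0, drift_sd_uV=0.0),
                              between_subject_cv=0.0, seed=5)
        cohort = simulate_cohort(config)
        ctrl = [rec for rec in cohort.values() if rec["group"] == "control"]
        a = ctrl[0]["sweeps"]["OD"][0].amplitude_uV
        b = ctrl[1]["sweeps"]["OS"][3].amplitude_uV
        np.testing.assert_array_equal(a, b)

    def test_group_mean_converges_to_preset(self, nf_presets):
        """Monte-Carlo: extracted a-wave amplitudes average to the preset mean."""
        base = nf_presets["control_DA10"]
        rng_master = 31
        amps = []
        n = 24
        for i in range(n):
            rng = np.random.default_rng(np.random.SeedSequence(rng_master, spawn_key=(i,)))
            p = draw_subject_params(base, 0.2, rng)
            amps.append(extract_wave_features(generate_trace(p, 1000.0, "DA10")).a_amp_uV)
        se = 0.2 * abs(base.a_amp_uV) / np.sqrt(n)
        assert np.mean(amps) == pytest.approx(base.a_amp_uV, abs=3 * se)

    def test_achm_preset_attenuates_high_band_but_not_to_zero(self, nf_presets):
        ctrl, achm = nf_presets["control_DA3"], nf_presets["achm_DA3"]
        assert ctrl.op_high.amp_uV > achm.op_high.amp_uV > 0
        t_ctrl = generate_trace(ctrl, 5000.0, "DA3")
        t_achm = generate_trace(achm, 5000.0, "DA3")
        sel = (t_ctrl.time_ms > 0) & (t_ctrl.time_ms < 50)
        rms = lambda tr: np.sqrt(np.mean(subband_trace(tr, "high").amplitude_uV[sel] ** 2))
        assert rms(t_achm) > 0
        assert rms(t_ctrl) / rms(t_achm) > 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(1, 2, "DA10", 1000.0, preset("control", "DA10"),
                         preset("achm", "DA10"))
        with pytest.raises(ParameterError):
            WaveformParams(-100.0, 50.0, 200.0, 45.0, OpBurst(85, 20, 1, 8),
                           OpBurst(160, 28, 1, 6))
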