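"""Synthetic dark-adapted ERG cohorts.

The generative model is deliberately phenomenological, not biophysical: a
narrow negative Gaussian lobe stands in for the photoreceptor a-wave, a wide
positive Gaussian lobe for the ON-bipolar b-wave, and two Gabor atoms for the
oscillatory-potential bursts (an early ~85 Hz burst and a later, faster burst
above 120 Hz, both inside the first 50 ms after the flash).  Gaussian lobes
make trough/peak placement analytically controllable, so a cohort can be
parameterized directly by published group means for amplitudes and implicit
times and those numbers are exactly recoverable by the downstream feature
extractor.

Because the lobes and bursts overlap in time, lobe gain and center are
calibrated jointly (damped fixed-point iteration on a dense grid) so that the
*composite* trace has its trough at exactly (a_amp_uV, a_time_ms) and its
trough-to-peak excursion equal to b_amp_uV with the peak at b_time_ms.

The achromatopsia presets reduce a/b amplitudes and prolong implicit times to
the published patient means, attenuate the high-frequency burst to 25% of the
control amplitude and delay it by 3 ms, and mildly attenuate the low band —
the "strongly reduced but not absent" high-band activity the analysis is
meant to detect.  Burst amplitudes themselves are package presets (no
published per-burst amplitudes exist), documented in docs/methods.md.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .errors import CalibrationError, ParameterError
from .trace_io import (CONDITIONS, EYES, GROUPS, SWEEPS_PER_EYE, CohortManifest,
                       ERGTrace, time_grid, write_manifest, write_trace)

EPOCH_MS = (-100.0, 250.0)

# grid step (ms) for the dense continuous-model calibration
_CAL_DT_MS = 0.02


@dataclass(frozen=True)
class OpBurst:
    """One oscillatory-potential burst: a Gabor atom on the composite."""

    center_freq_hz: float
    center_time_ms: float
    amp_uV: float
    sigma_ms: float


@dataclass(frozen=True)
class WaveformParams:
    """Population-level shape parameters for one group x condition."""

    a_amp_uV: float          # baseline-to-trough, negative
    a_time_ms: float         # a-wave implicit time
    b_amp_uV: float          # trough-to-peak, positive
    b_time_ms: float         # b-wave implicit time
    op_low: OpBurst
    op_high: OpBurst
    noise_sd_uV: float = 10.0
    drift_sd_uV: float = 5.0
    a_sigma_ms: float = 5.0  # lobe widths; free shape parameters (a kept wide
                             # enough that the lobes stay out of the 75-300 Hz OP band)
    b_sigma_ms: float = 12.0

    def __post_init__(self) -> None:
        if not self.a_amp_uV < 0:
            raise ParameterError("a_amp_uV must be negative (baseline-to-trough)")
        if not self.b_amp_uV > 0:
            raise ParameterError("b_amp_uV must be positive (trough-to-peak)")
        if not self.a_time_ms < self.b_time_ms:
            raise ParameterError("a_time_ms must precede b_time_ms")
        if not 70.0 <= self.op_low.center_freq_hz <= 100.0:
            raise ParameterError("op_low center frequency must lie in [70, 100] Hz")
        if not 120.0 <= self.op_high.center_freq_hz <= 200.0:
            raise ParameterError("op_high center frequency must lie in [120, 200] Hz")
        for burst in (self.op_low, self.op_high):
            if not burst.center_time_ms < 50.0:
                raise ParameterError("OP bursts must be centered before 50 ms")
            if burst.amp_uV < 0 or burst.sigma_ms <= 0:
                raise ParameterError("OP burst amplitude must be >= 0 and sigma > 0")
        if self.noise_sd_uV < 0 or self.drift_sd_uV < 0:
            raise ParameterError("noise/drift SDs must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition description for one simulated cohort."""

    n_control: int
    n_achm: int
    condition: str
    fs_hz: float
    control_params: WaveformParams
    achm_params: WaveformParams
    between_subject_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_achm < 2:
            raise ParameterError("need at least 2 subjects per group")
        if self.between_subject_cv < 0:
            raise ParameterError("between_subject_cv must be >= 0")
        if self.condition not in CONDITIONS:
            raise ParameterError(f"condition must be one of {CONDITIONS}")


_CONTROL_OP_LOW = OpBurst(85.0, 20.0, 25.0, 8.0)
_CONTROL_OP_HIGH = OpBurst(160.0, 28.0, 20.0, 6.0)
_ACHM_OP_LOW = OpBurst(85.0, 20.0, 25.0 * 0.85, 8.0)
_ACHM_OP_HIGH = OpBurst(160.0, 31.0, 20.0 * 0.25, 6.0)

#: group-mean presets; a/b entries are published group means, bursts are package presets
PRESETS: dict[str, WaveformParams] = {
    "control_DA3": WaveformParams(-264.8, 14.6, 449.8, 48.4, _CONTROL_OP_LOW, _CONTROL_OP_HIGH),
    "achm_DA3": WaveformParams(-185.0, 16.20, 324.17, 53.33, _ACHM_OP_LOW, _ACHM_OP_HIGH),
    "control_DA10": WaveformParams(-302.57, 11.07, 456.50, 47.38, _CONTROL_OP_LOW, _CONTROL_OP_HIGH),
    "achm_DA10": WaveformParams(-219.99, 12.35, 344.96, 49.14, _ACHM_OP_LOW, _ACHM_OP_HIGH),
}

#: published feature-level group mean/SD table used for distribution-level simulations
FEATURE_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("control", "DA3"): {"a_amp_uV": (-264.8, 61.8), "a_time_ms": (14.6, 1.08),
                         "b_amp_uV": (449.8, 107.49), "b_time_ms": (48.4, 4.10)},
    ("achm", "DA3"): {"a_amp_uV": (-185.0, 50.9), "a_time_ms": (16.20, 1.48),
                      "b_amp_uV": (324.17, 93.0), "b_time_ms": (53.33, 5.3)},
    ("control", "DA10"): {"a_amp_uV": (-302.57, 65.6), "a_time_ms": (11.07, 0.9),
                          "b_amp_uV": (456.50, 116.47), "b_time_ms": (47.38, 4.8)},
    ("achm", "DA10"): {"a_amp_uV": (-219.99, 60.7), "a_time_ms": (12.35, 1.0),
                       "b_amp_uV": (344.96, 91.8), "b_time_ms": (49.14, 4.6)},
}

#: native acquisition sampling rates per flash strength
CONDITION_FS: dict[str, float] = {"DA3": 5000.0, "DA10": 1000.0}


def preset(group: str, condition: str) -> WaveformParams:
    return PRESETS[f"{group}_{condition}"]


def _lobe(time_ms: np.ndarray, amp: float, center_ms: float, sigma_ms: float) -> np.ndarray:
    out = amp * np.exp(-((time_ms - center_ms) ** 2) / (2.0 * sigma_ms**2))
    out[time_ms <= 0] = 0.0
    return out


def make_component_awave(params: WaveformParams, time_ms: np.ndarray) -> np.ndarray:
    """Negative Gaussian lobe with its minimum exactly at (a_amp_uV, a_time_ms)."""
    return _lobe(np.asarray(time_ms, float), params.a_amp_uV, params.a_time_ms, params.a_sigma_ms)


def make_component_bwave(params: WaveformParams, time_ms: np.ndarray,
                         gain: float | None = None, center_ms: float | None = None) -> np.ndarray:
    """Positive Gaussian lobe; gain/center default to the calibrated values."""
    if gain is None or center_ms is None:
        _, _, cal_gain, cal_center = calibrate_composite(params)
        gain = cal_gain if gain is None else gain
        center_ms = cal_center if center_ms is None else center_ms
    return _lobe(np.asarray(time_ms, float), gain, center_ms, params.b_sigma_ms)


def make_op_burst(burst: OpBurst, time_ms: np.ndarray) -> np.ndarray:
    """Gabor atom: cosine at center_freq under a Gaussian envelope, zero pre-flash."""
    t = np.asarray(time_ms, float)
    env = burst.amp_uV * np.exp(-((t - burst.center_time_ms) ** 2) / (2.0 * burst.sigma_ms**2))
    out = env * np.cos(2.0 * np.pi * burst.center_freq_hz * (t - burst.center_time_ms) / 1000.0)
    out[t <= 0] = 0.0
    return out


def _assemble(params: WaveformParams, time_ms: np.ndarray,
              a_gain: float, a_center: float, b_gain: float, b_center: float) -> np.ndarray:
    y = _lobe(time_ms, a_gain, a_center, params.a_sigma_ms)
    y += _lobe(time_ms, b_gain, b_center, params.b_sigma_ms)
    y += make_op_burst(params.op_low, time_ms)
    y += make_op_burst(params.op_high, time_ms)
    return y


def _refine_extremum(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic 3-point refinement of an extremum at grid index i."""
    if i <= 0 or i >= y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return float(t[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def _measure_trough_peak(t: np.ndarray, y: np.ndarray,
                         a_window: tuple[float, float] = (3.0, 35.0),
                         t_max: float = 120.0):
    """Composite trough and subsequent dominant peak, sub-grid refined."""
    a_sel = np.where((t > a_window[0]) & (t <= a_window[1]))[0]
    if a_sel.size == 0 or np.min(y[a_sel]) >= 0:
        raise CalibrationError("composite has no negative trough in the a-wave window")
    i_tr = a_sel[np.argmin(y[a_sel])]
    tt, tv = _refine_extremum(t, y, i_tr)
    b_sel = np.where((t > t[i_tr]) & (t <= t_max))[0]
    interior = b_sel[(b_sel > 0) & (b_sel < y.size - 1)]
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1]) \
        & ((y[interior] > y[interior - 1]) | (y[interior] > y[interior + 1]))
    peaks = interior[is_max]
    if peaks.size == 0:
        if b_sel.size == 0:
            raise CalibrationError("no samples after the trough")
        i_pk = b_sel[np.argmax(y[b_sel])]      # endpoint fallback during iteration
        return tv, tt, float(y[i_pk]), float(t[i_pk])
    i_pk = peaks[np.argmax(y[peaks])]
    pt, pv = _refine_extremum(t, y, i_pk)
    return tv, tt, pv, pt


@lru_cache(maxsize=512)
def calibrate_composite(params: WaveformParams,
                        tol_uV: float = 0.005, tol_ms: float = 0.02,
                        max_iter: int = 500) -> tuple[float, float, float, float]:
    """Solve for (a_gain, a_center, b_gain, b_center) on the continuous model.

    Damped fixed-point iteration: each lobe's gain absorbs the value residual
    at its extremum, each center the timing residual.  Converges because the
    lobe curvature dominates the burst ripple at both extrema.
    """
    t_end = max(150.0, params.b_time_ms + 6.0 * params.b_sigma_ms)
    t = np.arange(int(-5.0 / _CAL_DT_MS), int(t_end / _CAL_DT_MS) + 1) * _CAL_DT_MS
    target_peak = params.a_amp_uV + params.b_amp_uV
    a_gain, a_center = params.a_amp_uV, params.a_time_ms
    b_gain, b_center = max(target_peak, 1.0), params.b_time_ms
    # upfront feasibility: without the b lobe the composite max (a-lobe tail
    # plus OP ripple) must not already exceed the trough-to-peak target
    y0 = _assemble(params, t, a_gain, a_center, 0.0, b_center)
    _, _, peak0, _ = _measure_trough_peak(t, y0, t_max=t_end)
    if target_peak < peak0 - tol_uV:
        raise CalibrationError(
            "trough-to-peak target lies below the OP ripple; the composite "
            "peak cannot be calibrated down to it")
    damp_ac = damp_bc = 0.7
    prev_tt = prev_pt = None
    best = None
    best_err = np.inf
    for _ in range(max_iter):
        y = _assemble(params, t, a_gain, a_center, b_gain, b_center)
        tv, tt, pv, pt = _measure_trough_peak(t, y, t_max=t_end)
        res_tv, res_tt = params.a_amp_uV - tv, params.a_time_ms - tt
        res_pv, res_pt = target_peak - pv, params.b_time_ms - pt
        # with a vanishing b lobe the peak time is unidentifiable; only the
        # peak *value* target remains meaningful
        b_identifiable = b_gain > 0.01
        if not b_identifiable:
            res_pt = 0.0
        if (abs(res_tv) < tol_uV and abs(res_pv) < tol_uV
                and abs(res_tt) < tol_ms and abs(res_pt) < tol_ms):
            return a_gain, a_center, b_gain, b_center
        err = max(abs(res_tv), abs(res_pv)) + 0.1 * max(abs(res_tt), abs(res_pt))
        if err < best_err:
            best_err = err
            best = (a_gain, a_center, b_gain, b_center,
                    max(abs(res_tv), abs(res_pv)), max(abs(res_tt), abs(res_pt)))
        # halve a center step whenever its residual changes sign (ripple ties
        # make the argmax jump discontinuously between neighbouring OP peaks)
        if prev_tt is not None and res_tt * prev_tt < 0:
            damp_ac = max(0.5 * damp_ac, 0.02)
        if prev_pt is not None and res_pt * prev_pt < 0:
            damp_bc = max(0.5 * damp_bc, 0.02)
        prev_tt, prev_pt = res_tt, res_pt
        a_gain += res_tv
        a_center += damp_ac * res_tt
        if b_gain == 0.0 and res_pv < -tol_uV:
            raise CalibrationError(
                "composite peak exceeds the trough-to-peak target even without a "
                "b lobe; targets infeasible")
        b_gain = max(b_gain + res_pv, 0.0)
        if b_identifiable:
            b_center += damp_bc * res_pt
        if a_gain >= 0:
            raise CalibrationError("a-lobe gain driven non-negative; targets infeasible")
    # an extremum target can sit in an OP-ripple trough, where no composite
    # argmax exists; accept the nearest attainable peak if amplitudes matched
    if best is not None and best[4] < 0.05 and best[5] < 3.0:
        return best[:4]
    raise CalibrationError("lobe calibration did not converge")


def composite_trace(params: WaveformParams, time_ms: np.ndarray) -> np.ndarray:
    """Deterministic noise-free composite on an arbitrary grid."""
    a_gain, a_center, b_gain, b_center = calibrate_composite(params)
    return _assemble(params, np.asarray(time_ms, float), a_gain, a_center, b_gain, b_center)


def _drift(rng: np.random.Generator, fs_hz: float, n: int, sd_uV: float) -> np.ndarray:
    """Band-limited (<5 Hz) baseline wander with the requested sample SD."""
    white = rng.standard_normal(n)
    sos = signal.butter(2, 5.0, btype="lowpass", fs=fs_hz, output="sos")
    low = signal.sosfiltfilt(sos, white)
    s = np.std(low)
    return low * (sd_uV / s) if s > 0 else np.zeros(n)


def generate_trace(params: WaveformParams, fs_hz: float, condition: str,
                   seed=None, meta: dict | None = None) -> ERGTrace:
    """One raw sweep: calibrated composite plus white noise and slow drift."""
    t = time_grid(fs_hz, *EPOCH_MS)
    y = composite_trace(params, t)
    if params.noise_sd_uV > 0 or params.drift_sd_uV > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if params.noise_sd_uV > 0:
            y = y + rng.normal(0.0, params.noise_sd_uV, t.size)
        if params.drift_sd_uV > 0:
            y = y + _drift(rng, fs_hz, t.size, params.drift_sd_uV)
    return ERGTrace(t, y, fs_hz, condition, dict(meta or {}))


# ---------------------------------------------------------------------------
# cohort-level simulation

#: times vary far less between subjects than amplitudes (published CVs ~7% vs ~23%)
TIME_CV_RATIO = 0.3

#: fraction of amplitude variance carried by a shared response-scale factor.
#: Component amplitudes co-vary strongly within a subject (electrode position,
#: media opacity, global response size); fully independent draws would produce
#: impossible morphologies such as a b-peak buried under the OP ripple.
AMP_SHARED_VAR_FRACTION = 0.8


def _ln_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0


def _ln_factor(rng: np.random.Generator, sigma: float) -> float:
    """Multiplicative lognormal jitter with unit mean."""
    if sigma <= 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def draw_subject_params(base: WaveformParams, cv: float, rng: np.random.Generator) -> WaveformParams:
    """Subject-level parameter draw: lognormal multiplicative jitter, sign preserved.

    Amplitudes share one subject-level scale factor plus smaller independent
    per-component factors (total CV equals ``cv``); times jitter independently
    at a reduced CV.
    """
    s2 = _ln_sigma(cv) ** 2
    s_shared = np.sqrt(AMP_SHARED_VAR_FRACTION * s2)
    s_comp = np.sqrt((1.0 - AMP_SHARED_VAR_FRACTION) * s2)
    s_t = _ln_sigma(TIME_CV_RATIO * cv)
    shared = _ln_factor(rng, s_shared)
    a_amp = base.a_amp_uV * shared * _ln_factor(rng, s_comp)
    b_amp = base.b_amp_uV * shared * _ln_factor(rng, s_comp)
    low_amp = base.op_low.amp_uV * shared * _ln_factor(rng, s_comp)
    high_amp = base.op_high.amp_uV * shared * _ln_factor(rng, s_comp)
    a_time = base.a_time_ms * _ln_factor(rng, s_t)
    b_time = base.b_time_ms * _ln_factor(rng, s_t)
    low_t = base.op_low.center_time_ms * _ln_factor(rng, s_t)
    high_t = base.op_high.center_time_ms * _ln_factor(rng, s_t)
    b_time = max(b_time, a_time + 3.0)
    low_t = min(low_t, 49.0)
    high_t = min(high_t, 49.0)
    return replace(base,
                   a_amp_uV=a_amp, a_time_ms=a_time, b_amp_uV=b_amp, b_time_ms=b_time,
                   op_low=replace(base.op_low, amp_uV=low_amp, center_time_ms=low_t),
                   op_high=replace(base.op_high, amp_uV=high_amp, center_time_ms=high_t))


def _stream(master_seed: int, *spawn_key: int) -> np.random.Generator:
    """Counter-based child stream: stable under subject/sweep reordering."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))


def simulate_cohort(config: CohortConfig) -> dict[str, dict]:
    """In-memory cohort: {subject_id: {"group", "params", "sweeps": {eye: [ERGTrace x5]}}}."""
    out: dict[str, dict] = {}
    group_specs = [("control", config.n_control, config.control_params),
                   ("achm", config.n_achm, config.achm_params)]
    for g_idx, (group, n, base) in enumerate(group_specs):
        for s_idx in range(n):
            subject = f"{'C' if group == 'control' else 'A'}{s_idx + 1:03d}"
            p_rng = _stream(config.seed, g_idx, s_idx)
            params = draw_subject_params(base, config.between_subject_cv, p_rng)
            sweeps: dict[str, list[ERGTrace]] = {}
            for e_idx, eye in enumerate(EYES):
                sweeps[eye] = []
                for sweep in range(1, SWEEPS_PER_EYE + 1):
                    rng = _stream(config.seed, g_idx, s_idx, e_idx, sweep)
                    meta = {"subject": subject, "group": group, "eye": eye, "sweep": str(sweep)}
                    sweeps[eye].append(
                        generate_trace(params, config.fs_hz, config.condition, rng, meta))
            out[subject] = {"group": group, "params": params, "sweeps": sweeps}
    return out


def generate_cohort(config: CohortConfig, out_dir: str) -> CohortManifest:
    """Write a full cohort (trace files + manifest + provenance JSON) to out_dir."""
    cohort = simulate_cohort(config)
    traces_dir = os.path.join(out_dir, "traces")
    os.makedirs(traces_dir, exist_ok=True)
    rows = []
    for subject, rec in cohort.items():
        for eye, traces in rec["sweeps"].items():
            for i, trace in enumerate(traces, start=1):
                rel = os.path.join("traces", f"{subject}_{config.condition}_{eye}_{i}.tsv")
                write_trace(trace, os.path.join(out_dir, rel))
                rows.append({"subject_id": subject, "group": rec["group"],
                             "condition": config.condition, "eye": eye,
                             "sweep_index": i, "trace_path": rel})
    manifest = CohortManifest(pd.DataFrame(rows), root=out_dir)
    write_manifest(manifest, os.path.join(out_dir, "manifest.tsv"))
    _write_provenance(config, cohort, os.path.join(out_dir, "simulation.json"))
    return manifest


def _params_dict(p: WaveformParams) -> dict:
    d = {k: getattr(p, k) for k in ("a_amp_uV", "a_time_ms", "b_amp_uV", "b_time_ms",
                                    "noise_sd_uV", "drift_sd_uV", "a_sigma_ms", "b_sigma_ms")}
    for name in ("op_low", "op_high"):
        burst = getattr(p, name)
        d[name] = {k: getattr(burst, k) for k in
                   ("center_freq_hz", "center_time_ms", "amp_uV", "sigma_ms")}
    return d


def _write_provenance(config: CohortConfig, cohort: dict, path: str) -> None:
    record = {
        "n_control": config.n_control, "n_achm": config.n_achm,
        "condition": config.condition, "fs_hz": config.fs_hz,
        "between_subject_cv": config.between_subject_cv, "seed": config.seed,
        "control_params": _params_dict(config.control_params),
        "achm_params": _params_dict(config.achm_params),
        "subjects": {s: {"group": rec["group"], "params": _params_dict(rec["params"])}
                     for s, rec in cohort.items()},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
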