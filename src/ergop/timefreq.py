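"""Complex Morlet scalograms of ERG traces in baseline-relative dB.

The mother wavelet is a Gabor atom, e^{i2πft}·e^{−t²/2s²}, whose Gaussian SD
is tied to the analysis frequency through s = n/(2πf).  The cycle count n
rises log-linearly from 3 at 10 Hz to 7 at 300 Hz, trading temporal sharpness
at low frequencies for spectral sharpness at high ones.  Power is the squared
magnitude of the linear convolution of the trace with each kernel; each
frequency row is then divided by its mean pre-stimulus (baseline) power and
converted to dB (10·log10), which cancels amplifier gain and any
per-frequency kernel scaling.  Points within two temporal SDs of either epoch
edge are flagged invalid (cone of influence) rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError
from .trace_io import ERGTrace

FREQ_RANGE = (10.0, 300.0)
CYCLE_RANGE = (3.0, 7.0)

#: default analysis and baseline windows (ms)
ANALYSIS_WINDOW = (-20.0, 100.0)
BASELINE_WINDOW = (-20.0, 0.0)

#: minimum epoch span (ms) required for an edge-safe analysis window
EPOCH_SPAN = (-100.0, 250.0)

_POWER_FLOOR = 1e-30


def cycles_for_freqs(freqs_hz, f_range=FREQ_RANGE, n_range=CYCLE_RANGE) -> np.ndarray:
    """Cycle count per frequency: log n linear in log f, 3 at 10 Hz to 7 at 300 Hz."""
    f = np.asarray(freqs_hz, dtype=float)
    lo, hi = f_range
    if np.any(f < lo - 1e-9) or np.any(f > hi + 1e-9):
        raise ParameterError(f"analysis frequencies must lie within [{lo}, {hi}] Hz")
    frac = (np.log(f) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return np.exp(np.log(n_range[0]) + (np.log(n_range[1]) - np.log(n_range[0])) * frac)


@dataclass(frozen=True)
class WaveletSpec:
    """Frequency grid, per-frequency cycle counts and Gaussian SDs."""

    freqs_hz: np.ndarray
    n_cycles: np.ndarray
    sigma_s: np.ndarray
    fs_hz: float
    support_sd: float = 4.0

    @classmethod
    def default(cls, fs_hz: float, f_min: float = 10.0, f_max: float = 300.0,
                f_step: float = 2.0, n_range=CYCLE_RANGE, support_sd: float = 4.0,
                f_range=FREQ_RANGE) -> "WaveletSpec":
        freqs = np.arange(f_min, f_max + f_step / 2, f_step, dtype=float)
        freqs = freqs[freqs <= f_max + 1e-9]
        n = cycles_for_freqs(freqs, f_range=f_range, n_range=n_range)
        return cls(freqs, n, n / (2.0 * np.pi * freqs), float(fs_hz), support_sd)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, float)
        if np.any(np.diff(f) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(f >= self.fs_hz / 2):
            raise ParameterError("analysis frequency at or above Nyquist")


def morlet_kernel(f_hz: float, n_cycles: float, fs_hz: float,
                  support_sd: float = 4.0, normalize: bool = True) -> np.ndarray:
    """Sampled complex Morlet atom, truncated at ±support_sd·s.

    Normalized to unit gain at the center frequency (the Fourier transform at
    f_hz equals 1), so a sinusoid at the analysis frequency passes with
    frequency-independent magnitude.  The scaling cancels in the baseline
    ratio regardless; unit gain additionally keeps raw-power comparisons
    across frequencies unbiased.
    """
    if f_hz >= fs_hz / 2:
        raise ParameterError(f"kernel frequency {f_hz} Hz at or above Nyquist")
    s = n_cycles / (2.0 * np.pi * f_hz)
    half = int(np.ceil(support_sd * s * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    w = np.exp(2j * np.pi * f_hz * t) * np.exp(-(t**2) / (2.0 * s**2))
    if normalize:
        # gain at f_hz = sum of the (real, positive) envelope times dt
        w = w / (np.sum(np.abs(w)) / fs_hz)
    return w


def cwt_power(trace: ERGTrace, spec: WaveletSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw wavelet power (time x frequency) with an edge-validity mask."""
    t = trace.time_ms
    if t[0] > EPOCH_SPAN[0] + 1e-6 or t[-1] < EPOCH_SPAN[1] - 1e-6:
        raise ParameterError(
            f"trace must span at least [{EPOCH_SPAN[0]}, {EPOCH_SPAN[1]}] ms so the "
            "analysis window stays clear of edge effects at the lowest frequencies")
    y = trace.amplitude_uV
    n_t, n_f = t.size, len(spec.freqs_hz)
    power = np.empty((n_t, n_f))
    valid = np.empty((n_t, n_f), dtype=bool)
    for k, (f, n) in enumerate(zip(spec.freqs_hz, spec.n_cycles)):
        kernel = morlet_kernel(f, n, trace.fs_hz, spec.support_sd)
        if kernel.size > 10 * n_t:
            raise ParameterError(
                f"wavelet at {f} Hz is over 10x longer than the trace; record longer epochs")
        resp = signal.fftconvolve(y.astype(complex), kernel, mode="same")
        power[:, k] = np.abs(resp) ** 2
        margin_ms = 2.0 * spec.sigma_s[k] * 1000.0
        valid[:, k] = (t - t[0] >= margin_ms) & (t[-1] - t >= margin_ms)
    return power, valid


@dataclass
class Scalogram:
    """Baseline-relative power map (dB) on a time x frequency grid."""

    power_db: np.ndarray
    time_ms: np.ndarray
    freqs_hz: np.ndarray
    baseline_window_ms: tuple[float, float]
    valid_mask: np.ndarray
    subject_id: str | None = None
    group: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.time_ms.size, self.freqs_hz.size):
            raise ParameterError("power_db shape must be (n_times, n_freqs)")
        if self.valid_mask.shape != self.power_db.shape:
            raise ParameterError("valid_mask shape must match power_db")
        if not self.baseline_window_ms[1] <= 0:
            raise ParameterError("baseline window must precede stimulus onset")
        if not np.all(np.isfinite(self.power_db[self.valid_mask])):
            raise ParameterError("non-finite dB power at valid points")


def to_decibel(power: np.ndarray, time_ms: np.ndarray, freqs_hz: np.ndarray,
               valid_mask: np.ndarray,
               baseline_window: tuple[float, float] = BASELINE_WINDOW,
               **identity) -> Scalogram:
    """Per-frequency baseline division and 10·log10 transform."""
    lo, hi = baseline_window
    if hi > 0:
        raise ParameterError("baseline window must be pre-stimulus")
    base_sel = (time_ms >= lo) & (time_ms < hi)
    if not np.any(base_sel):
        raise ParameterError("baseline window contains no samples")
    baseline = np.maximum(power[base_sel].mean(axis=0), _POWER_FLOOR)
    db = 10.0 * np.log10(np.maximum(power, _POWER_FLOOR) / baseline)
    return Scalogram(db, np.asarray(time_ms, float), np.asarray(freqs_hz, float),
                     (lo, hi), valid_mask, **identity)


def subject_scalogram(trace: ERGTrace, spec: WaveletSpec | None = None,
                      baseline_window: tuple[float, float] = BASELINE_WINDOW,
                      window: tuple[float, float] = ANALYSIS_WINDOW) -> Scalogram:
    """CWT on the full epoch, dB-normalized, cropped to the analysis window."""
    if spec is None:
        spec = WaveletSpec.default(trace.fs_hz)
    power, valid = cwt_power(trace, spec)
    scal = to_decibel(power, trace.time_ms, spec.freqs_hz, valid, baseline_window,
                      subject_id=trace.meta.get("subject"), group=trace.meta.get("group"),
                      condition=trace.condition)
    sel = (scal.time_ms >= window[0]) & (scal.time_ms <= window[1])
    return Scalogram(scal.power_db[sel], scal.time_ms[sel], scal.freqs_hz,
                     scal.baseline_window_ms, scal.valid_mask[sel],
                     scal.subject_id, scal.group, scal.condition)


def group_mean_scalogram(scalograms: list[Scalogram]) -> Scalogram:
    """Pointwise mean of per-subject dB maps; validity is the AND of inputs."""
    if not scalograms:
        raise ParameterError("no scalograms to average")
    ref = scalograms[0]
    for s in scalograms[1:]:
        if (s.time_ms.shape != ref.time_ms.shape or s.freqs_hz.shape != ref.freqs_hz.shape
                or not np.allclose(s.time_ms, ref.time_ms)
                or not np.allclose(s.freqs_hz, ref.freqs_hz)):
            raise ParameterError("scalogram axes mismatch")
    mean = np.mean([s.power_db for s in scalograms], axis=0)
    mask = np.logical_and.reduce([s.valid_mask for s in scalograms])
    groups = {s.group for s in scalograms}
    return Scalogram(mean, ref.time_ms.copy(), ref.freqs_hz.copy(), ref.baseline_window_ms,
                     mask, subject_id=None, group=groups.pop() if len(groups) == 1 else None,
                     condition=ref.condition)


def stack_maps(scalograms: list[Scalogram]) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects, T, F) dB stack and the combined validity mask."""
    if not scalograms:
        raise ParameterError("no scalograms to stack")
    maps = np.stack([s.power_db for s in scalograms])
    mask = np.logical_and.reduce([s.valid_mask for s in scalograms])
    return maps, mask
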