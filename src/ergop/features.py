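"""Time-domain ERG measures: a-/b-wave features, OP traces, sub-band traces.

The a-wave is the most negative trough after flash onset (amplitude measured
baseline-to-trough, so it is negative); the b-wave is the dominant positive
peak that follows it, with amplitude measured trough-to-peak by the usual
clinical convention (configurable to baseline-referenced).  Implicit times
run from flash onset to the respective extremum and are refined below the
sample grid by parabolic interpolation.  Oscillatory potentials are isolated
by a zero-phase 75–300 Hz band-pass; the two sub-band traces (50–100 Hz and
150–200 Hz) separate the early low-frequency burst from the late
high-frequency one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FeatureExtractionError, ParameterError
from .preprocess import FilterSpec, bandpass, subject_trace
from .trace_io import CohortManifest, ERGTrace

logger = logging.getLogger(__name__)

#: named sub-bands of the OP range (Hz)
BANDS: dict[str, tuple[float, float]] = {"low": (50.0, 100.0), "high": (150.0, 200.0)}

OP_BAND = (75.0, 300.0)

#: default search windows (ms): trough in (3, 35], peak after the trough up to 120
A_WINDOW = (3.0, 35.0)
B_WINDOW_END = 120.0


@dataclass
class WaveFeatures:
    a_amp_uV: float
    a_time_ms: float
    b_amp_uV: float
    b_time_ms: float
    condition: str
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.a_time_ms < self.b_time_ms:
            raise FeatureExtractionError("a-wave implicit time must precede b-wave")
        if not self.b_amp_uV > 0:
            raise FeatureExtractionError("b-wave amplitude must be positive")
        for t in (self.a_time_ms, self.b_time_ms):
            if not 0 < t <= 120.0:
                raise FeatureExtractionError("implicit times must lie in (0, 120] ms")


def _refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i <= 0 or i >= y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(t[i] + delta * (t[1] - t[0])), float(y1 - 0.25 * (y0 - y2) * delta)


def extract_wave_features(trace: ERGTrace,
                          a_window: tuple[float, float] = A_WINDOW,
                          b_window_end: float = B_WINDOW_END,
                          b_amp_ref: str = "trough") -> WaveFeatures:
    """Locate the a-trough and subsequent b-peak of a subject-averaged trace."""
    if b_amp_ref not in ("trough", "baseline"):
        raise ParameterError("b_amp_ref must be 'trough' or 'baseline'")
    t, y = trace.time_ms, trace.amplitude_uV
    a_sel = np.where((t > a_window[0]) & (t <= a_window[1]))[0]
    if a_sel.size == 0 or np.min(y[a_sel]) >= 0:
        raise FeatureExtractionError("a-wave not detected: no trough below baseline "
                                     f"in ({a_window[0]}, {a_window[1]}] ms")
    i_tr = a_sel[np.argmin(y[a_sel])]
    a_time, a_amp = _refine(t, y, i_tr)

    b_sel = np.where((t > t[i_tr]) & (t <= b_window_end))[0]
    interior = b_sel[(b_sel > 0) & (b_sel < y.size - 1)]
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1]) \
        & ((y[interior] > y[interior - 1]) | (y[interior] > y[interior + 1]))
    peaks = interior[is_max]
    if peaks.size == 0:
        raise FeatureExtractionError("b-wave not detected: no local maximum after the trough")
    # the largest local maximum in the window; earliest sample wins ties
    i_pk = peaks[np.argmax(y[peaks])]
    b_time, b_peak = _refine(t, y, i_pk)
    b_amp = b_peak - a_amp if b_amp_ref == "trough" else b_peak
    return WaveFeatures(a_amp, a_time, b_amp, b_time, trace.condition,
                        subject_id=trace.meta.get("subject"), group=trace.meta.get("group"))


def _clipped_band(fs_hz: float, low: float, high: float) -> tuple[float, float]:
    limit = 0.45 * fs_hz
    if high >= limit:
        logger.warning("band edge %g Hz too close to Nyquist at fs=%g Hz; clipping to %g Hz",
                       high, fs_hz, limit)
        high = limit
    if low >= high:
        raise ParameterError(f"sampling rate {fs_hz} Hz too low for a {low} Hz band edge")
    return low, high


def extract_ops(trace: ERGTrace, order: int = 4) -> ERGTrace:
    """Oscillatory-potentials trace: zero-phase 75–300 Hz band-pass."""
    low, high = _clipped_band(trace.fs_hz, *OP_BAND)
    return bandpass(trace, FilterSpec(low, high, order))


def subband_trace(trace: ERGTrace, band, order: int = 4) -> ERGTrace:
    """Band-limited trace for a named ('low'/'high') or explicit (lo, hi) band."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    lo, hi = _clipped_band(trace.fs_hz, lo, hi)
    return bandpass(trace, FilterSpec(lo, hi, order))


def features_table(manifest: CohortManifest, condition: str,
                   spec: FilterSpec = FilterSpec(), **extract_kwargs) -> pd.DataFrame:
    """Per-subject WaveFeatures for one condition, as a tidy DataFrame."""
    rows = []
    for subject in manifest.subjects():
        feats = extract_wave_features(subject_trace(manifest, subject, condition, spec),
                                      **extract_kwargs)
        rows.append({"subject_id": subject, "group": manifest.group_of(subject),
                     "condition": condition, "a_amp_uV": feats.a_amp_uV,
                     "a_time_ms": feats.a_time_ms, "b_amp_uV": feats.b_amp_uV,
                     "b_time_ms": feats.b_time_ms})
    return pd.DataFrame(rows)


def group_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD per feature, one row per group x condition."""
    value_cols = ["a_amp_uV", "a_time_ms", "b_amp_uV", "b_time_ms"]
    agg = features.groupby(["group", "condition"])[value_cols].agg(["mean", "std", "count"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()
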