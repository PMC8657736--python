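"""Acquisition-side conditioning: band-pass filtering and sweep/eye averaging.

The clinical recording chain band-limits each sweep to 0.3–300 Hz, averages
the five sweeps of each eye into one response, and averages the two eyes into
a single per-subject trace.  Filtering is zero-phase (forward-backward
Butterworth) so component implicit times are not biased by group delay; the
filter family and order are package conventions, since only the bandwidth is
standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError
from .trace_io import CohortManifest, ERGTrace, TIME_TOL_MS, read_trace


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 0.3
    high_hz: float = 300.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ParameterError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs_hz / 2:
            raise ParameterError(
                f"high edge {self.high_hz} Hz is at or above Nyquist ({fs_hz / 2} Hz)")

    @property
    def label(self) -> str:
        phase = "zerophase" if self.zero_phase else "causal"
        return f"butter{self.order}_{self.low_hz:g}-{self.high_hz:g}Hz_{phase}"


def bandpass(trace: ERGTrace, spec: FilterSpec = FilterSpec()) -> ERGTrace:
    """Zero-phase Butterworth band-pass; same length and time axis."""
    spec.validate(trace.fs_hz)
    sos = signal.butter(spec.order, (spec.low_hz, spec.high_hz), btype="bandpass",
                        fs=trace.fs_hz, output="sos")
    y = trace.amplitude_uV
    if spec.zero_phase:
        # odd signal extension, long enough to absorb the low-edge transient
        padlen = min(y.size - 1, max(3 * 2 * sos.shape[0], int(0.25 * trace.fs_hz / spec.low_hz)))
        out = signal.sosfiltfilt(sos, y, padtype="odd", padlen=padlen)
    else:
        out = signal.sosfilt(sos, y)
    return trace.with_amplitude(out, filter=spec.label)


def _check_compatible(traces: list[ERGTrace]) -> None:
    ref = traces[0]
    for tr in traces[1:]:
        if tr.fs_hz != ref.fs_hz or tr.condition != ref.condition:
            raise ParameterError("traces differ in sampling rate or condition")
        if tr.time_ms.shape != ref.time_ms.shape or \
                np.max(np.abs(tr.time_ms - ref.time_ms)) > TIME_TOL_MS:
            raise ParameterError("traces have mismatched time axes")


def _common_meta(traces: list[ERGTrace]) -> dict:
    keys = set.intersection(*(set(t.meta) for t in traces)) if traces else set()
    return {k: traces[0].meta[k] for k in keys
            if all(t.meta[k] == traces[0].meta[k] for t in traces)}


def average_sweeps(traces: list[ERGTrace]) -> ERGTrace:
    """Pointwise mean across repeated sweeps of one eye."""
    if not traces:
        raise ParameterError("no traces to average")
    _check_compatible(traces)
    mean = np.mean([t.amplitude_uV for t in traces], axis=0)
    meta = _common_meta(traces)
    meta["sweep"] = "avg"
    return ERGTrace(traces[0].time_ms.copy(), mean, traces[0].fs_hz, traces[0].condition, meta)


def average_eyes(od: ERGTrace, os_: ERGTrace) -> ERGTrace:
    """Pointwise mean of the two per-eye averaged responses."""
    _check_compatible([od, os_])
    mean = 0.5 * (od.amplitude_uV + os_.amplitude_uV)
    meta = _common_meta([od, os_])
    meta["eye"] = "both"
    return ERGTrace(od.time_ms.copy(), mean, od.fs_hz, od.condition, meta)


def subject_trace_from_sweeps(sweeps_by_eye: dict[str, list[ERGTrace]],
                              spec: FilterSpec = FilterSpec()) -> ERGTrace:
    """Filter every sweep, average within each eye, then across eyes."""
    if set(sweeps_by_eye) != {"OD", "OS"}:
        raise ParameterError(f"need sweeps for both eyes, got {sorted(sweeps_by_eye)}")
    per_eye = {eye: average_sweeps([bandpass(t, spec) for t in traces])
               for eye, traces in sweeps_by_eye.items()}
    return average_eyes(per_eye["OD"], per_eye["OS"])


def subject_trace(manifest: CohortManifest, subject: str, condition: str,
                  spec: FilterSpec = FilterSpec()) -> ERGTrace:
    """One averaged trace per subject and condition, loaded via the manifest."""
    sweeps_by_eye: dict[str, list[ERGTrace]] = {}
    for eye in ("OD", "OS"):
        rows = manifest.rows_for(subject, condition, eye)
        if rows.empty:
            raise ParameterError(f"subject {subject!r} has no {eye} sweeps for {condition}")
        rows = rows.sort_values("sweep_index")
        sweeps_by_eye[eye] = [read_trace(manifest.full_path(p)) for p in rows["trace_path"]]
    out = subject_trace_from_sweeps(sweeps_by_eye, spec)
    out.meta.update(subject=subject, group=manifest.group_of(subject))
    return out
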