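"""Domain containers and plain-text file formats for full-field ERG sweeps.

A trace file is a self-describing TSV: ``#``-prefixed ``key=value`` header
lines, a two-column header row, then one ``time_ms<TAB>amplitude_uV`` row per
sample.  Times are in milliseconds relative to flash onset (onset is itself a
sample), amplitudes in microvolts.  A cohort manifest is a TSV listing every
(subject, group, condition, eye, sweep) with the path of its trace file.
Both formats round-trip byte-identically, which keeps fixtures diff-able.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ManifestValidationError, TraceFormatError

CONDITIONS = ("DA3", "DA10")
EYES = ("OD", "OS")
GROUPS = ("control", "achm")
SWEEPS_PER_EYE = 5

#: tolerance on sampling-grid uniformity, in ms
TIME_TOL_MS = 1e-9

_COLUMNS_HEADER = "time_ms\tamplitude_uV"
MANIFEST_COLUMNS = ["subject_id", "group", "condition", "eye", "sweep_index", "trace_path"]


def time_grid(fs_hz: float, start_ms: float = -100.0, end_ms: float = 250.0) -> np.ndarray:
    """Uniform sample grid containing flash onset (t = 0) as a sample."""
    dt = 1000.0 / fs_hz
    k0 = int(round(start_ms / dt))
    k1 = int(round(end_ms / dt))
    return np.arange(k0, k1 + 1, dtype=np.float64) * dt


@dataclass
class ERGTrace:
    """One uniformly sampled ERG voltage time series, anchored at flash onset."""

    time_ms: np.ndarray
    amplitude_uV: np.ndarray
    fs_hz: float
    condition: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.amplitude_uV = np.asarray(self.amplitude_uV, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.amplitude_uV.shape:
            raise TraceFormatError("time and amplitude must be 1-D vectors of equal length")
        if self.condition not in CONDITIONS:
            raise TraceFormatError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.time_ms.size < 3:
            raise TraceFormatError("trace must contain at least 3 samples")
        dt = 1000.0 / self.fs_hz
        diffs = np.diff(self.time_ms)
        if np.any(diffs <= 0):
            raise TraceFormatError("time_ms must be strictly increasing")
        bad = np.abs(diffs - dt) > TIME_TOL_MS
        if np.any(bad):
            raise TraceFormatError(
                f"non-uniform sampling: sample interval at index {int(np.argmax(bad))} "
                f"deviates from 1000/fs_hz = {dt} ms"
            )
        if np.min(np.abs(self.time_ms)) > TIME_TOL_MS:
            raise TraceFormatError("flash onset (t = 0) must be a sample")
        if not np.all(np.isfinite(self.amplitude_uV)):
            raise TraceFormatError("amplitude_uV contains non-finite values")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.time_ms)))

    def with_amplitude(self, amplitude_uV: np.ndarray, **meta_updates) -> "ERGTrace":
        """Copy of this trace with a new amplitude vector and updated meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return ERGTrace(self.time_ms.copy(), np.asarray(amplitude_uV, dtype=np.float64),
                        self.fs_hz, self.condition, meta)


def _format_fs(fs_hz: float) -> str:
    return str(int(fs_hz)) if float(fs_hz).is_integer() else repr(float(fs_hz))


def write_trace(trace: ERGTrace, path: str) -> None:
    """Canonical serialization: header, column names, 6-decimal data rows."""
    trace.validate()
    lines = [f"# fs_hz={_format_fs(trace.fs_hz)}", f"# condition={trace.condition}"]
    for key in sorted(trace.meta):
        lines.append(f"# {key}={trace.meta[key]}")
    lines.append(_COLUMNS_HEADER)
    for t, v in zip(trace.time_ms, trace.amplitude_uV):
        lines.append(f"{t:.6f}\t{v:.6f}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trace(path: str) -> ERGTrace:
    """Parse a canonical trace file, naming the offending line on failure."""
    meta: dict = {}
    fs_hz = None
    condition = None
    times: list[float] = []
    amps: list[float] = []
    saw_columns = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "fs_hz":
                    try:
                        fs_hz = float(value)
                    except ValueError:
                        raise TraceFormatError(f"{path}:{lineno}: fs_hz is not a number: {value!r}")
                elif key == "condition":
                    condition = value
                else:
                    meta[key] = value
                continue
            if not saw_columns:
                if line != _COLUMNS_HEADER:
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected column header {_COLUMNS_HEADER!r}, got {line!r}"
                    )
                saw_columns = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                amps.append(float(parts[1]))
            except ValueError:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric data row {line!r}")
    if fs_hz is None:
        raise TraceFormatError(f"{path}: missing required header 'fs_hz'")
    if condition is None:
        raise TraceFormatError(f"{path}: missing required header 'condition'")
    if not saw_columns:
        raise TraceFormatError(f"{path}: missing column header row")
    time_ms = np.array(times)
    dt = 1000.0 / fs_hz
    diffs = np.diff(time_ms)
    bad = np.abs(diffs - dt) > TIME_TOL_MS
    if np.any(bad):
        # +2 header offset: column row comes right before the first data row
        first_data_line = lineno - len(times) + 1
        raise TraceFormatError(
            f"{path}:{first_data_line + int(np.argmax(bad)) + 1}: non-uniform sampling "
            f"(interval deviates from {dt} ms)"
        )
    return ERGTrace(time_ms, np.array(amps), fs_hz, condition, meta)


@dataclass
class CohortManifest:
    """Subject x group x condition x eye x sweep index of trace files."""

    table: pd.DataFrame
    root: str = "."

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise ManifestValidationError(f"manifest missing columns: {missing}")
        bad_groups = sorted(set(t["group"]) - set(GROUPS))
        if bad_groups:
            raise ManifestValidationError(f"unknown group labels: {bad_groups}")
        bad_eyes = sorted(set(t["eye"]) - set(EYES))
        if bad_eyes:
            raise ManifestValidationError(f"unknown eye labels: {bad_eyes}")
        offenders = []
        for subj, sub in t.groupby("subject_id"):
            if sub["group"].nunique() != 1:
                offenders.append(f"{subj}: inconsistent group labels")
            for cond, cond_sub in sub.groupby("condition"):
                eyes = set(cond_sub["eye"])
                if eyes != set(EYES):
                    offenders.append(f"{subj}/{cond}: eyes {sorted(eyes)} (need both OD and OS)")
                for eye, eye_sub in cond_sub.groupby("eye"):
                    sweeps = sorted(eye_sub["sweep_index"].astype(int))
                    if sweeps != list(range(1, SWEEPS_PER_EYE + 1)):
                        offenders.append(f"{subj}/{cond}/{eye}: sweeps {sweeps} (need 1..{SWEEPS_PER_EYE})")
        if offenders:
            raise ManifestValidationError("invalid manifest: " + "; ".join(offenders))

    def subjects(self, group: str | None = None) -> list[str]:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        return sorted(t["subject_id"].unique())

    def group_of(self, subject: str) -> str:
        rows = self.table[self.table["subject_id"] == subject]
        if rows.empty:
            raise ManifestValidationError(f"subject {subject!r} not in manifest")
        return str(rows["group"].iloc[0])

    def rows_for(self, subject: str, condition: str, eye: str | None = None) -> pd.DataFrame:
        t = self.table
        sel = (t["subject_id"] == subject) & (t["condition"] == condition)
        if eye is not None:
            sel &= t["eye"] == eye
        return t[sel]

    def full_path(self, trace_path: str) -> str:
        return trace_path if os.path.isabs(trace_path) else os.path.join(self.root, trace_path)


def write_manifest(manifest: CohortManifest, path: str) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS,
                          lineterminator="\n")


def read_manifest(path: str) -> CohortManifest:
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str,
                                               "condition": str, "eye": str,
                                               "sweep_index": int, "trace_path": str})
    return CohortManifest(table, root=os.path.dirname(os.path.abspath(path)))
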