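"""Optional scalogram heatmaps; diagnostics only, never an input to analysis."""

from __future__ import annotations

import numpy as np

from .timefreq import Scalogram


def plot_scalogram(scal: Scalogram, path: str | None = None, ax=None, vmax: float | None = None):
    """Render a dB map (time on x, frequency on y); invalid points are blanked."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    db = np.where(scal.valid_mask, scal.power_db, np.nan)
    if vmax is None:
        vmax = float(np.nanmax(np.abs(db))) or 1.0
    mesh = ax.pcolormesh(scal.time_ms, scal.freqs_hz, db.T, cmap="RdBu_r",
                         vmin=-vmax, vmax=vmax, shading="nearest")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    title = " ".join(str(v) for v in (scal.group, scal.condition, scal.subject_id) if v)
    ax.set_title(title or "relative power (dB)")
    ax.figure.colorbar(mesh, ax=ax, label="relative power (dB)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
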