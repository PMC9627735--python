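"""Minimal plotting helpers: data with fitted-curve overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trace_fit", "plot_dose_series"]

_H = 3600.0


def plot_trace_fit(trace, fit=None, ax=None, path=None):
    """Plot one aggregation trace, optionally overlaying a sigmoid fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(trace.t / _H, trace.y, "x", ms=3, alpha=0.6, label="data")
    if fit is not None:
        tt = np.linspace(trace.t[0], trace.t[-1], 400)
        ax.plot(tt / _H, fit.predict(tt), "-", lw=1.5, label="fit")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("signal")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_dose_series(traces_by_ratio, ax=None, path=None):
    """Overlay normalized traces across inhibitor ratios (darker = higher)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ratios = sorted(traces_by_ratio)
    for i, r in enumerate(ratios):
        tr = traces_by_ratio[r]
        shade = 0.15 + 0.8 * i / max(len(ratios) - 1, 1)
        ax.plot(tr.t / _H, tr.y, color=plt.cm.Reds(shade), lw=1, label=f"{r:g}%")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized fibril mass")
    ax.legend(frameon=False, fontsize=8, title="inhibitor")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
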