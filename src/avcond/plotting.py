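"""Minimal plotting helpers for ROI ERPs and scalp topographies."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .design import ChannelLayout

__all__ = ["plot_roi_erps", "plot_topomap"]


def plot_roi_erps(times: np.ndarray, erps: Dict[str, np.ndarray], ax=None,
                  sig_mask: Optional[np.ndarray] = None):
    """Overlay labelled ERP traces (mean +/- SEM over subjects) for one ROI.

    ``erps`` maps trace labels to ``subjects x time`` arrays; an optional
    boolean ``sig_mask`` marks significant samples along the time axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, data in erps.items():
        data = np.atleast_2d(data)
        mean = data.mean(axis=0)
        sem = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0]) \
            if data.shape[0] > 1 else np.zeros_like(mean)
        ax.plot(times, mean, label=label)
        ax.fill_between(times, mean - sem, mean + sem, alpha=0.25)
    if sig_mask is not None and sig_mask.any():
        y0 = ax.get_ylim()[0]
        ax.plot(times[sig_mask], np.full(sig_mask.sum(), y0), ".", ms=3,
                color="k")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.legend(frameon=False)
    return ax


def plot_topomap(layout: ChannelLayout, values: np.ndarray, ax=None,
                 cmap: str = "RdBu_r"):
    """Scatter-style scalp map of one value per channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.asarray(values, dtype=float)
    lim = np.abs(values).max() or 1.0
    sc = ax.scatter(layout.pos2d[:, 0], layout.pos2d[:, 1], c=values,
                    s=220, cmap=cmap, vmin=-lim, vmax=lim,
                    edgecolors="k", linewidths=0.5)
    for name, (x, y) in zip(layout.names, layout.pos2d):
        ax.annotate(name, (x, y), ha="center", va="center", fontsize=5)
    ax.set_aspect("equal")
    ax.axis("off")
    return sc
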