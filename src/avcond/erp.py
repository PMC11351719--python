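"""ROI-averaged event-related potentials and learning-phase contrasts.

ERPs are computed per subject as the mean over trials of a condition and then
over the channels of a predefined region of interest; contrasts between
conditions or learning phases are per-timepoint paired differences handed to
the cluster permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .epochs import EpochSet

__all__ = ["RoiMap", "DEFAULT_ROIS", "roi_erp", "erp_contrast", "topographic_bins"]


@dataclass
class RoiMap:
    """The three channel groups used for regional averaging."""

    frontal: List[str] = field(default_factory=lambda: [
        "Fpz", "Fz", "F3", "F4", "F7", "F8", "F9", "F10"])
    temporo_parietal: List[str] = field(default_factory=lambda: [
        "FC5", "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP6", "P7", "P3", "Pz"])
    parieto_occipital: List[str] = field(default_factory=lambda: [
        "P4", "P8", "PO7", "PO8", "O1", "Oz", "O2"])

    def __post_init__(self) -> None:
        groups = [self.frontal, self.temporo_parietal, self.parieto_occipital]
        flat = [ch for g in groups for ch in g]
        if len(flat) != len(set(flat)):
            raise ValueError("ROIs must be disjoint")

    def items(self):
        return (("frontal", self.frontal),
                ("temporo_parietal", self.temporo_parietal),
                ("parieto_occipital", self.parieto_occipital))

    def __getitem__(self, name: str) -> List[str]:
        return dict(self.items())[name]


DEFAULT_ROIS = RoiMap()


def roi_erp(epochs: EpochSet, trial_mask, roi_channels: Sequence[str]
            ) -> np.ndarray:
    """Mean over the selected trials, then over the ROI channels.

    Returns a time series on the epoch's time base.
    """
    sel = epochs.select(trial_mask)
    if sel.n_trials == 0:
        raise ValueError("empty trial selection")
    ch_idx = epochs.layout.index(roi_channels)
    return sel.data.mean(axis=0)[ch_idx].mean(axis=0)


def erp_contrast(erps_a: np.ndarray, erps_b: np.ndarray) -> np.ndarray:
    """Per-subject, per-timepoint paired differences A - B.

    Both inputs are ``subjects x time`` on identical time bases; the result
    feeds `avcond.stats.paired_cluster_test`.
    """
    a = np.atleast_2d(np.asarray(erps_a, dtype=float))
    b = np.atleast_2d(np.asarray(erps_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"mismatched shapes {a.shape} vs {b.shape}")
    return a - b


def topographic_bins(epochs: EpochSet, trial_mask, bin_ms: float = 100.0,
                     t_min: Optional[float] = None,
                     t_max: Optional[float] = None) -> Dict[float, np.ndarray]:
    """Trial-averaged per-channel topographies over consecutive time bins.

    Returns ``{bin start (ms): per-channel mean amplitude}``; averaging the
    map over a bin's samples commutes with trial averaging, so the maps
    integrate to the underlying per-channel means.
    """
    sel = epochs.select(trial_mask)
    avg = sel.data.mean(axis=0)  # channels x time
    t0 = epochs.times[0] if t_min is None else t_min
    t1 = epochs.times[-1] if t_max is None else t_max
    out = {}
    start = t0
    while start < t1:
        mask = epochs.time_mask(start, min(start + bin_ms, t1 + 1e-9))
        if mask.any():
            out[start] = avg[:, mask].mean(axis=1)
        start += bin_ms
    return out
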