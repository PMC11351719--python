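"""The epoched-EEG container used throughout the pipeline."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .design import ChannelLayout

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Trials x channels x time EEG amplitudes with aligned trial metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_times)`` in microvolts.
    times:
        Sample times in ms relative to the auditory onset, uniform at
        ``1000 / srate``.
    srate:
        Sampling rate in Hz.
    layout:
        Channel layout; ``layout.names`` indexes the channel axis.
    meta:
        One schedule row per trial (same order as ``data``).
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    layout: ChannelLayout
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta must have one row per trial")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("channel axis does not match layout")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.srate, rtol=1e-6, atol=1e-6):
                raise ValueError("times must be uniform at 1/srate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.srate,
                        self.layout, self.meta.copy())

    def select(self, trial_mask) -> "EpochSet":
        """Subset trials by boolean mask or index array (metadata follows)."""
        idx = np.asarray(trial_mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return EpochSet(self.data[idx], self.times, self.srate, self.layout,
                        self.meta.iloc[idx].reset_index(drop=True))

    def time_mask(self, t_min: float, t_max: float) -> np.ndarray:
        """Boolean mask over samples in the half-open window [t_min, t_max)."""
        return (self.times >= t_min) & (self.times < t_max)

    def save(self, path) -> None:
        """Write to a self-describing HDF5 container."""
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data, compression="gzip")
            fh.create_dataset("times", data=self.times)
            fh.attrs["srate"] = float(self.srate)
            fh.attrs["layout"] = json.dumps({
                "names": self.layout.names,
                "pos2d": self.layout.pos2d.tolist(),
                "pos3d": self.layout.pos3d.tolist(),
                "neighbors": self.layout.neighbors,
            })
            buf = io.StringIO()
            self.meta.to_csv(buf, index=False)
            fh.attrs["meta"] = buf.getvalue()

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as fh:
            lay = json.loads(fh.attrs["layout"])
            layout = ChannelLayout(
                names=lay["names"],
                pos2d=np.asarray(lay["pos2d"]),
                pos3d=np.asarray(lay["pos3d"]),
                neighbors={k: list(v) for k, v in lay["neighbors"].items()},
            )
            meta = pd.read_csv(io.StringIO(fh.attrs["meta"]))
            return cls(fh["data"][()], fh["times"][()], float(fh.attrs["srate"]),
                       layout, meta)
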