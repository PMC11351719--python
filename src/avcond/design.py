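"""Experimental design: trial schedules and the 27-channel scalp layout.

The paradigm is an implicit audio-visual sensory-conditioning session: on every
non-target trial one of two equiprobable pure tones (A1, A2) is followed, after
a short gap, by a Gabor patch or by nothing.  The two tones carry opposite
contingencies -- A1 is followed by its Gabor (V1) on 90% of trials, A2 by its
Gabor (V2) on only 10% -- so the tones become predictive of visual stimulus
presence versus absence.  A handful of perceptual targets (the only
task-relevant events) are interleaved in each block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "ChannelLayout",
    "CHANNEL_NAMES",
    "generate_schedule",
    "default_layout",
    "read_schedule",
    "write_schedule",
]

#: The 27 Ag/AgCl electrode sites of the montage (10-5 nomenclature).
CHANNEL_NAMES: List[str] = [
    "Fpz", "Fz", "F3", "F4", "F7", "F8", "F9", "F10",
    "FC5", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO8", "O1", "Oz", "O2",
]

NON_TARGET_TYPES = ("A1-trial", "A2-trial")
TARGET_TYPES = ("audio-target", "visual-target")


@dataclass
class DesignConfig:
    """Session structure and stimulus timing.

    Defaults reproduce the conditioning session: 400 trials in 10 blocks,
    4 targets per block, 90/10 contingencies, 600 ms tones, a 50 ms gap to a
    500 ms visual stimulus, and a 2500 +/- 500 ms inter-trial interval.
    """

    n_blocks: int = 10
    trials_per_block: int = 40
    targets_per_block: int = 4
    p_v_given_a1: float = 0.9
    p_v_given_a2: float = 0.1
    fixation_ms: float = 100.0
    pre_audio_ms: float = 500.0
    audio_ms: float = 600.0
    gap_ms: float = 50.0
    visual_ms: float = 500.0
    iti_mean_ms: float = 2500.0
    iti_jitter_ms: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_v_given_a1", "p_v_given_a2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must lie in [0, 1]")
        for name in ("fixation_ms", "pre_audio_ms", "audio_ms", "gap_ms",
                     "visual_ms", "iti_mean_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iti_jitter_ms < 0:
            raise ValueError("iti_jitter_ms must be non-negative")
        if self.targets_per_block >= self.trials_per_block:
            raise ValueError("targets_per_block must be < trials_per_block")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")


def generate_schedule(config: DesignConfig) -> pd.DataFrame:
    """Generate one session's trial schedule.

    Non-target trials are split evenly between the two tones and shuffled;
    visual outcomes are drawn i.i.d. per trial with the configured conditional
    probabilities; targets occupy random positions within each block.  Onset
    columns hold absolute session times in ms.  Deterministic given
    ``config.seed``.

    Returns a DataFrame with columns ``trial_id, block, trial_type,
    visual_outcome, audio_onset_ms, visual_onset_ms, iti_ms``; onsets that do
    not apply (e.g. the visual onset of a target trial) are NaN.
    """
    rng = np.random.default_rng(config.seed)
    n_nt = config.trials_per_block - config.targets_per_block

    rows = []
    t_clock = 0.0
    trial_id = 0
    for block in range(config.n_blocks):
        half = n_nt // 2
        types = ["A1-trial"] * half + ["A2-trial"] * half
        if n_nt % 2:
            types.append(NON_TARGET_TYPES[rng.integers(2)])
        rng.shuffle(types)
        # insert targets at random positions within the block
        for _ in range(config.targets_per_block):
            pos = rng.integers(len(types) + 1)
            types.insert(pos, TARGET_TYPES[rng.integers(2)])

        for ttype in types:
            stim_t = t_clock + config.fixation_ms + config.pre_audio_ms
            iti = config.iti_mean_ms + rng.uniform(-1.0, 1.0) * config.iti_jitter_ms
            audio_onset = np.nan
            visual_onset = np.nan
            if ttype == "A1-trial":
                outcome = "V1" if rng.random() < config.p_v_given_a1 else "V0"
            elif ttype == "A2-trial":
                outcome = "V2" if rng.random() < config.p_v_given_a2 else "V0"
            else:
                outcome = "n/a"
            if ttype in NON_TARGET_TYPES:
                audio_onset = stim_t
                visual_onset = stim_t + config.audio_ms + config.gap_ms
            elif ttype == "audio-target":
                audio_onset = stim_t
            else:  # visual-target
                visual_onset = stim_t
            rows.append({
                "trial_id": trial_id,
                "block": block,
                "trial_type": ttype,
                "visual_outcome": outcome,
                "audio_onset_ms": audio_onset,
                "visual_onset_ms": visual_onset,
                "iti_ms": iti,
            })
            trial_end = stim_t + config.audio_ms + config.gap_ms + config.visual_ms
            t_clock = trial_end + iti
            trial_id += 1
    return pd.DataFrame(rows)


def write_schedule(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False)


def read_schedule(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class ChannelLayout:
    """Electrode names, scalp coordinates and a neighbourhood graph.

    ``pos2d`` is an azimuthal-equidistant projection of the 3-D head-frame
    positions (x rightwards, y towards the nasion); ``neighbors`` maps each
    channel to the labels within a fixed multiple of the median
    nearest-neighbour distance.
    """

    names: List[str]
    pos2d: np.ndarray
    pos3d: np.ndarray
    neighbors: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate channel names")
        if self.pos2d.shape != (len(self.names), 2):
            raise ValueError("pos2d must be (n_channels, 2)")
        if self.pos3d.shape != (len(self.names), 3):
            raise ValueError("pos3d must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, names) -> np.ndarray:
        """Indices of the given channel labels."""
        lut = {n: i for i, n in enumerate(self.names)}
        return np.array([lut[n] for n in names], dtype=int)

    def to_json(self, path) -> None:
        payload = {
            "names": self.names,
            "pos2d": self.pos2d.tolist(),
            "pos3d": self.pos3d.tolist(),
            "neighbors": self.neighbors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ChannelLayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            names=payload["names"],
            pos2d=np.asarray(payload["pos2d"]),
            pos3d=np.asarray(payload["pos3d"]),
            neighbors={k: list(v) for k, v in payload["neighbors"].items()},
        )


# Factor applied to the median nearest-neighbour distance when building the
# adjacency graph; on this sparse 27-site montage it leaves every channel with
# at least two neighbours and the vertex Cz with four.
_NEIGHBOR_FACTOR = 1.75


def default_layout() -> ChannelLayout:
    """The 27-channel montage with standard 10-5 positions and neighbour map."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            montage = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older naming
            montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    pos3d = np.array([ch_pos[name] for name in CHANNEL_NAMES])

    # azimuthal-equidistant projection onto the plane (Cz maps to the origin)
    r = np.linalg.norm(pos3d, axis=1)
    polar = np.arccos(np.clip(pos3d[:, 2] / r, -1.0, 1.0))
    azim = np.arctan2(pos3d[:, 1], pos3d[:, 0])
    pos2d = np.column_stack([polar * np.cos(azim), polar * np.sin(azim)])

    dist = np.linalg.norm(pos3d[:, None] - pos3d[None, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    thr = _NEIGHBOR_FACTOR * np.median(dist.min(axis=1))
    neighbors = {
        name: [CHANNEL_NAMES[j] for j in np.nonzero(dist[i] < thr)[0]]
        for i, name in enumerate(CHANNEL_NAMES)
    }
    return ChannelLayout(names=list(CHANNEL_NAMES), pos2d=pos2d, pos3d=pos3d,
                         neighbors=neighbors)


def design_to_dict(config: DesignConfig) -> dict:
    return asdict(config)
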