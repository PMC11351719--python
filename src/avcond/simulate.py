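"""Synthetic evoked-EEG sessions with controllable learning effects.

No public recordings exist for this paradigm, so the generator plants the
phenomena the analysis chain is built to recover, over realistic spatially
correlated 1/f background activity:

* evoked responses to the tone (fronto-central) and the Gabor (occipital),
  both attenuating linearly with trial position (expectation suppression);
* a growing injection of the visual-evoked pattern into the audio period of
  tone-A1 trials, so that late audio-period patterns resemble visual-period
  patterns (the pattern-similarity effect, and the only source of A1/A2
  decodability);
* single-trial amplitude in a post-visual window linearly coupled to a
  supplied precision-weighted prediction-error trajectory.

All effect sizes are explicit `SynthEffects` fields so each downstream stage
can be tested in the noiseless limit and at realistic signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .design import ChannelLayout, DesignConfig, NON_TARGET_TYPES
from .epochs import EpochSet

__all__ = ["SynthEffects", "default_effects", "simulate_session",
           "attenuation_factor", "injection_gain"]

EPOCH_WINDOW_MS = (-300.0, 1300.0)


@dataclass
class SynthEffects:
    """Evoked templates, learning-effect magnitudes and noise parameters.

    ``attenuation_rate`` is the fractional amplitude decline from the mean of
    the first third of trials to the mean of the last third;
    ``similarity_gain`` is the fraction of the visual template injected into
    the audio period at the end of the session (the injection ramps linearly
    from zero); ``pwpe_coupling`` is in microvolt per unit pwPE over
    ``pwpe_window_ms`` (relative to the visual onset).
    """

    auditory_template: np.ndarray
    visual_template: np.ndarray
    template_srate: float
    attenuation_rate: float = 0.3
    similarity_gain: float = 0.6
    pwpe_coupling: float = 15.0
    pwpe_profile: Optional[np.ndarray] = None  # per-channel weights, peak 1
    noise_sd: float = 6.0
    white_sd: float = 1.5
    pink_exponent: float = 1.0
    line_noise_amp: float = 0.0
    line_hz: float = 50.0
    inj_onset_ms: float = 200.0
    pwpe_window_ms: Tuple[float, float] = (250.0, 550.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation_rate <= 1.0:
            raise ValueError("attenuation_rate must lie in [0, 1]")
        if not 0.0 <= self.similarity_gain <= 1.0:
            raise ValueError("similarity_gain must lie in [0, 1]")
        if self.noise_sd < 0 or self.white_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


def _gauss_bump(t_ms: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / width) ** 2)


def _spatial_profile(layout: ChannelLayout, center_name: str,
                     sigma: float) -> np.ndarray:
    center = layout.pos2d[layout.names.index(center_name)]
    d = np.linalg.norm(layout.pos2d - center, axis=1)
    return np.exp(-0.5 * (d / sigma) ** 2)


def default_effects(layout: ChannelLayout, srate: float = 500.0,
                    **overrides) -> SynthEffects:
    """Rank-one evoked templates on the given layout.

    The auditory response is a fronto-central biphasic N1/P2-like waveform
    (peak ~4 uV) spanning the 600 ms tone; the visual response is an occipital
    P1/N2-like waveform (peak ~4 uV) spanning the 500 ms Gabor.
    """
    t_aud = np.arange(0.0, 600.0, 1000.0 / srate)
    aud_wave = (-4.0 * _gauss_bump(t_aud, 100.0, 25.0)
                + 2.5 * _gauss_bump(t_aud, 200.0, 40.0))
    aud_profile = _spatial_profile(layout, "Cz", 0.45)

    t_vis = np.arange(0.0, 500.0, 1000.0 / srate)
    vis_wave = (4.0 * _gauss_bump(t_vis, 120.0, 30.0)
                - 2.0 * _gauss_bump(t_vis, 250.0, 50.0))
    vis_profile = _spatial_profile(layout, "Oz", 0.6)

    overrides.setdefault("pwpe_profile", vis_profile)
    return SynthEffects(
        auditory_template=np.outer(aud_profile, aud_wave),
        visual_template=np.outer(vis_profile, vis_wave),
        template_srate=srate,
        **overrides,
    )


def attenuation_factor(pos: np.ndarray, rate: float) -> np.ndarray:
    """Linear amplitude factor over normalised trial position ``pos`` in [0,1].

    Parameterised so that the factor averages 1 over the first third of the
    session and ``1 - rate`` over the last third, matching the phase-contrast
    semantics of ``attenuation_rate``.
    """
    return 1.0 + 0.25 * rate - 1.5 * rate * np.asarray(pos, dtype=float)


def injection_gain(pos: np.ndarray, gain: float) -> np.ndarray:
    """Visual-template injection gain, ramping linearly from 0 to ``gain``."""
    return gain * np.asarray(pos, dtype=float)


def _pink_noise(rng: np.random.Generator, n_series: int, n_times: int,
                srate: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise series (spectral shaping)."""
    white = rng.standard_normal((n_series, n_times))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n_times, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _mixing_matrix(layout: ChannelLayout, lam: float = 0.12) -> np.ndarray:
    """Channel x source mixing for spatially correlated noise (unit rows)."""
    d = np.linalg.norm(layout.pos3d[:, None] - layout.pos3d[None, :], axis=-1)
    mix = np.exp(-0.5 * (d / lam) ** 2)
    return mix / np.linalg.norm(mix, axis=1, keepdims=True)


def simulate_session(
    schedule: pd.DataFrame,
    layout: ChannelLayout,
    effects: SynthEffects,
    pwpe: Optional[Dict[str, np.ndarray]] = None,
    seed: int = 0,
    config: Optional[DesignConfig] = None,
) -> EpochSet:
    """Simulate epoched EEG (-300..1300 ms around stimulus onset) for a session.

    Parameters
    ----------
    pwpe:
        Optional mapping from auditory condition label (``"A1"``/``"A2"``) to
        a per-trial pwPE vector aligned, in order, to the non-target trials of
        that condition.
    config:
        Timing configuration; defaults to `DesignConfig()` (used for the
        audio-to-visual latency).
    """
    config = config or DesignConfig()
    srate = effects.template_srate
    rng = np.random.default_rng(seed)
    dt = 1000.0 / srate
    times = np.arange(EPOCH_WINDOW_MS[0], EPOCH_WINDOW_MS[1], dt)
    n_times = times.size
    n_ch = layout.n_channels
    n_trials = len(schedule)
    visual_lat_ms = config.audio_ms + config.gap_ms

    # per-trial pwPE aligned to condition rows
    pwpe_values = np.zeros(n_trials)
    if pwpe:
        for cond, values in pwpe.items():
            rows = np.nonzero(schedule["trial_type"].to_numpy() == f"{cond}-trial")[0]
            values = np.asarray(values, dtype=float)
            if values.shape != (rows.size,):
                raise ValueError(
                    f"pwpe[{cond!r}] has length {values.size}, expected {rows.size}")
            pwpe_values[rows] = values

    # normalised position among non-target trials (targets keep factor 1)
    is_nt = schedule["trial_type"].isin(NON_TARGET_TYPES).to_numpy()
    pos = np.zeros(n_trials)
    n_nt = int(is_nt.sum())
    if n_nt > 1:
        pos[is_nt] = np.arange(n_nt) / (n_nt - 1)
    atten = np.where(is_nt, attenuation_factor(pos, effects.attenuation_rate), 1.0)
    inj = np.where(is_nt, injection_gain(pos, effects.similarity_gain), 0.0)

    def place(dest: np.ndarray, template: np.ndarray, onset_ms: float,
              scale: float, t_stop_ms: float = np.inf) -> None:
        start = int(round((onset_ms - EPOCH_WINDOW_MS[0]) / dt))
        stop = min(start + template.shape[1], n_times,
                   int(round((t_stop_ms - EPOCH_WINDOW_MS[0]) / dt))
                   if np.isfinite(t_stop_ms) else n_times)
        if stop <= start:
            return
        dest[:, start:stop] += scale * template[:, : stop - start]

    data = np.zeros((n_trials, n_ch, n_times))
    mix = _mixing_matrix(layout)
    pw_lo = visual_lat_ms + effects.pwpe_window_ms[0]
    pw_hi = visual_lat_ms + effects.pwpe_window_ms[1]
    pw_mask = (times >= pw_lo) & (times < pw_hi)
    line_gradient = 0.5 + (layout.pos2d[:, 1] - layout.pos2d[:, 1].min()) / np.ptp(
        layout.pos2d[:, 1])

    for i, row in enumerate(schedule.itertuples(index=False)):
        ttype = row.trial_type
        if ttype == "A1-trial" or ttype == "A2-trial":
            place(data[i], effects.auditory_template, 0.0, atten[i])
            if row.visual_outcome in ("V1", "V2"):
                place(data[i], effects.visual_template, visual_lat_ms, atten[i])
            if ttype == "A1-trial" and inj[i] > 0:
                # audio-period injection, truncated at the end of the tone+gap
                place(data[i], effects.visual_template, effects.inj_onset_ms,
                      inj[i], t_stop_ms=visual_lat_ms)
            if effects.pwpe_coupling != 0.0 and pwpe_values[i] != 0.0:
                profile = (np.ones(n_ch) if effects.pwpe_profile is None
                           else np.asarray(effects.pwpe_profile, dtype=float))
                data[i][:, pw_mask] += (effects.pwpe_coupling * pwpe_values[i]
                                        * profile[:, None])
        elif ttype == "audio-target":
            place(data[i], effects.auditory_template, 0.0, 1.0)
        else:  # visual-target
            place(data[i], effects.visual_template, 0.0, 1.0)

        if effects.noise_sd > 0:
            src = _pink_noise(rng, n_ch, n_times, srate, effects.pink_exponent)
            data[i] += effects.noise_sd * (mix @ src)
        if effects.white_sd > 0:
            data[i] += effects.white_sd * rng.standard_normal((n_ch, n_times))
        if effects.line_noise_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * effects.line_hz * times / 1000.0 + phase)
            data[i] += effects.line_noise_amp * np.outer(line_gradient, wave)

    return EpochSet(data=data, times=times, srate=srate, layout=layout,
                    meta=schedule.reset_index(drop=True))
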