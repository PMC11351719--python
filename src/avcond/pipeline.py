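"""End-to-end synthetic-cohort runs: simulate, preprocess, analyse.

This module wires the stages together the way the study design intends them
to be used: each simulated subject gets their own schedule, an ideal-observer
pwPE trajectory computed from that schedule, and a synthetic EEG session in
which attenuation, audio-visual pattern convergence and pwPE coupling are
planted; the cohort-level analyses then ask whether each effect is recovered
with cluster-corrected group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np

from .design import DesignConfig, default_layout, generate_schedule
from .decoding import decode_timecourse, empirical_chance
from .epochs import EpochSet
from .erp import DEFAULT_ROIS, erp_contrast, roi_erp
from .glm import fit_pwpe_glm
from .hgf import pwpe_per_condition
from .preprocess import PreprocConfig, preprocess_session, split_phases
from .simulate import default_effects, simulate_session
from .similarity import dissimilarity_matrix
from .stats import paired_cluster_test

__all__ = ["SubjectData", "simulate_subject", "simulate_cohort",
           "analyze_cohort", "AUDIO_PERIOD_MS", "VISUAL_ONSET_MS"]

AUDIO_PERIOD_MS = (0.0, 650.0)
VISUAL_ONSET_MS = 650.0


@dataclass
class SubjectData:
    """One simulated participant after preprocessing."""

    epochs: EpochSet              # clean 250 Hz epochs
    schedule: "object"            # the session schedule (DataFrame)
    pwpe: Dict[str, "object"]     # per-condition pwPE tables
    report: Dict


def simulate_subject(
    subject_seed: int,
    design: Optional[DesignConfig] = None,
    effects_overrides: Optional[Dict] = None,
    raw_srate: float = 500.0,
    subject_gain: float = 1.0,
    preproc: Optional[PreprocConfig] = None,
) -> SubjectData:
    """Simulate and preprocess one participant.

    The subject's own schedule drives both the EEG simulation and the
    ideal-observer pwPE trajectories (which, when ``pwpe_coupling`` is
    nonzero, are also the planted single-trial amplitude modulators).
    ``subject_gain`` scales the evoked templates to model between-subject
    amplitude variability.
    """
    design = design or DesignConfig()
    layout = default_layout()
    schedule = generate_schedule(replace(design, seed=subject_seed))
    pwpe = pwpe_per_condition(schedule)
    effects = default_effects(layout, srate=raw_srate,
                              **(effects_overrides or {}))
    effects.auditory_template = subject_gain * effects.auditory_template
    effects.visual_template = subject_gain * effects.visual_template
    epochs = simulate_session(
        schedule, layout, effects,
        pwpe={c: tbl["pwpe"].to_numpy() for c, tbl in pwpe.items()},
        seed=subject_seed + 7919, config=design)
    clean, report = preprocess_session(epochs, preproc)
    return SubjectData(epochs=clean, schedule=schedule, pwpe=pwpe,
                       report=report)


def simulate_cohort(n_subjects: int = 21, base_seed: int = 0,
                    subject_gain_sd: float = 0.1, **kwargs
                    ) -> List[SubjectData]:
    """Simulate a cohort; subject seeds are ``base_seed*1000 + i``."""
    rng = np.random.default_rng(base_seed)
    gains = 1.0 + subject_gain_sd * rng.standard_normal(n_subjects)
    return [simulate_subject(base_seed * 1000 + i, subject_gain=max(g, 0.2),
                             **kwargs)
            for i, g in enumerate(gains)]


def _condition_mask(epochs: EpochSet, trial_type: str,
                    outcome: Optional[str] = None) -> np.ndarray:
    mask = (epochs.meta["trial_type"] == trial_type).to_numpy()
    if outcome is not None:
        mask &= (epochs.meta["visual_outcome"] == outcome).to_numpy()
    return mask


def analyze_cohort(
    subjects: List[SubjectData],
    n_perm: int = 1000,
    seed: int = 0,
    roi_erp_name: str = "parieto_occipital",
    roi_dm_name: str = "parieto_occipital",
    roi_glm_name: str = "parieto_occipital",
    dm_step: int = 5,
    decode_step: int = 2,
) -> Dict:
    """Run the four group-level analyses on a simulated cohort.

    Returns a dict with, per analysis, the subject-level inputs, the
    `ClusterResult`, and the time bases needed to localise clusters:

    * ``erp``: initial-vs-final ROI ERP contrast for V1|A1 trials;
    * ``decoding``: A1-vs-A2 AUC minus empirical chance over the audio period;
    * ``psa``: final-minus-initial cvMD dissimilarity grids for V1|A1;
    * ``glm``: post-audio ROI R^2 minus the pre-visual baseline level.
    """
    rois = DEFAULT_ROIS
    first = subjects[0].epochs
    times = first.times
    audio_idx = np.nonzero((times >= AUDIO_PERIOD_MS[0])
                           & (times < AUDIO_PERIOD_MS[1]))[0][::decode_step]
    post_idx = np.nonzero(times >= VISUAL_ONSET_MS)[0]

    erp_diffs, auc_diffs, dm_diffs, glm_diffs = [], [], [], []
    dm_axes = None
    for k, sub in enumerate(subjects):
        ep = sub.epochs
        # --- ERP attenuation: V1|A1, initial vs final thirds
        v1a1 = np.nonzero(_condition_mask(ep, "A1-trial", "V1"))[0]
        phases = split_phases(np.zeros(v1a1.size, dtype=int))
        erp_init = roi_erp(ep, v1a1[phases["initial"]], rois[roi_erp_name])
        erp_fin = roi_erp(ep, v1a1[phases["final"]], rois[roi_erp_name])
        erp_diffs.append(erp_contrast(erp_fin, erp_init)[0])

        # --- decoding: A1 vs A2 over the audio period, against chance
        nt = _condition_mask(ep, "A1-trial") | _condition_mask(ep, "A2-trial")
        data = ep.data[np.ix_(np.nonzero(nt)[0],
                              np.arange(ep.layout.n_channels), audio_idx)]
        labels = ep.meta.loc[nt, "trial_type"].to_numpy()
        res = decode_timecourse(data, labels, seed=seed + k)
        chance = empirical_chance(data, labels, seed=seed + 10_000 + k)
        auc_diffs.append(res.auc - chance)

        # --- pattern similarity: final minus initial cvMD grids
        dms = {}
        for phase in ("initial", "final"):
            dm = dissimilarity_matrix(
                ep, v1a1[phases[phase]], rois[roi_dm_name],
                visual_onset_ms=VISUAL_ONSET_MS, seed=seed + k, step=dm_step)
            dms[phase] = dm
        dm_axes = (dms["final"].audio_times_ms, dms["final"].post_times_ms)
        dm_diffs.append(dms["final"].values - dms["initial"].values)

        # --- pwPE GLM: ROI R^2 versus pre-visual baseline
        a1 = _condition_mask(ep, "A1-trial")
        kept = ep.meta.loc[a1, "trial_id"].to_numpy()
        tbl = sub.pwpe["A1"].set_index("trial_id").loc[kept]
        # the pwPE tracks stimulus presence (rare omissions are surprising),
        # so presence is partialled out to isolate coupling beyond the
        # visual-evoked response itself
        presence = (ep.meta.loc[a1, "visual_outcome"] == "V1"
                    ).to_numpy(float)[:, None]
        glm = fit_pwpe_glm(ep.select(a1), tbl["pwpe"].to_numpy(),
                           visual_onset_ms=VISUAL_ONSET_MS,
                           confounds=presence)
        roi_tc = glm.roi_r2[roi_glm_name][post_idx]
        glm_diffs.append(roi_tc - glm.baseline_r2[roi_glm_name])

    out = {
        "times": times,
        "audio_times": times[audio_idx],
        "post_times": times[post_idx],
        "dm_axes": dm_axes,
        "erp": {"diffs": np.array(erp_diffs)},
        "decoding": {"diffs": np.array(auc_diffs)},
        "psa": {"diffs": np.array(dm_diffs)},
        "glm": {"diffs": np.array(glm_diffs)},
    }
    for i, name in enumerate(("erp", "decoding", "psa", "glm")):
        out[name]["clusters"] = paired_cluster_test(
            out[name]["diffs"], n_perm=n_perm, seed=seed + 555 + i)
    return out
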