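"""Trial-wise GLM coupling EEG amplitude to pwPE trajectories.

Single-trial amplitude at every channel-timepoint pair is regressed (ordinary
least squares, intercept + pwPE) on the model-derived precision-weighted
prediction error of that trial; the coefficient of determination R^2 maps
where and when the EEG tracks the ideal observer's belief updates.  R^2 is
invariant to affine rescaling of the regressor, so no standardisation is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .epochs import EpochSet
from .erp import RoiMap, DEFAULT_ROIS

__all__ = ["GlmResult", "PwpeGlm", "fit_pwpe_glm", "compare_conditions"]


@dataclass
class GlmResult:
    """R^2 maps, ROI-averaged time courses and the pre-visual baseline level."""

    r2: np.ndarray                  # (n_channels, n_times)
    roi_r2: Dict[str, np.ndarray]   # ROI name -> (n_times,)
    baseline_r2: Dict[str, float]   # ROI name -> mean pre-visual R^2
    times: np.ndarray


class PwpeGlm(BaseEstimator):
    """Mass-univariate single-regressor OLS of amplitude on pwPE.

    Parameters
    ----------
    rois:
        Channel groups over which R^2 is averaged.
    visual_onset_ms:
        Boundary of the baseline window: all samples before it count as
        baseline.

    Attributes
    ----------
    r2_ : ndarray (n_channels, n_times)
    roi_r2_ : dict of ROI time courses
    baseline_r2_ : dict of ROI baseline means
    """

    def __init__(self, rois: Optional[RoiMap] = None,
                 visual_onset_ms: float = 650.0):
        self.rois = rois
        self.visual_onset_ms = visual_onset_ms

    def fit(self, epochs: EpochSet, pwpe, confounds=None) -> "PwpeGlm":
        """Fit the mass-univariate regression.

        ``confounds``, if given, is a ``trials x k`` matrix of nuisance
        regressors (e.g. stimulus presence) projected out of both amplitude
        and pwPE before R^2 is computed, so the map reflects pwPE coupling
        beyond the confounds (a partial R^2).
        """
        x = np.asarray(pwpe, dtype=float)
        if x.ndim != 1 or x.size != epochs.n_trials:
            raise ValueError("pwpe must align with the surviving trials")
        if x.size < 3:
            raise ValueError("need at least 3 trials")
        rois = self.rois or DEFAULT_ROIS
        y = epochs.data                      # (trials, channels, times)
        if confounds is not None:
            c = np.column_stack([np.ones(x.size),
                                 np.atleast_2d(np.asarray(confounds, float).T).T])
            proj = c @ np.linalg.pinv(c)
            x = x - proj @ x
            y = y - np.einsum("ij,jct->ict", proj, y)
        xc = x - x.mean()
        yc = y - y.mean(axis=0)
        ssx = float(xc @ xc)
        ssy = np.einsum("ict,ict->ct", yc, yc)
        sxy = np.einsum("i,ict->ct", xc, yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = sxy ** 2 / (ssx * ssy)
        r2 = np.nan_to_num(r2, nan=0.0)      # zero-variance cells carry no fit
        self.r2_ = r2
        self.roi_r2_ = {name: r2[epochs.layout.index(chs)].mean(axis=0)
                        for name, chs in rois.items()}
        bl = epochs.times < self.visual_onset_ms
        self.baseline_r2_ = {name: float(tc[bl].mean())
                             for name, tc in self.roi_r2_.items()}
        self.times_ = epochs.times.copy()
        return self


def fit_pwpe_glm(epochs: EpochSet, pwpe, rois: Optional[RoiMap] = None,
                 visual_onset_ms: float = 650.0, confounds=None) -> GlmResult:
    """Functional wrapper over `PwpeGlm`."""
    est = PwpeGlm(rois=rois, visual_onset_ms=visual_onset_ms).fit(
        epochs, pwpe, confounds=confounds)
    return GlmResult(r2=est.r2_, roi_r2=est.roi_r2_,
                     baseline_r2=est.baseline_r2_, times=est.times_)


def compare_conditions(roi_r2_a: np.ndarray, roi_r2_b: np.ndarray
                       ) -> np.ndarray:
    """Per-subject, per-timepoint R^2 differences between two condition models.

    Inputs are ``subjects x time`` arrays of ROI-averaged R^2 for matched
    subjects; the antisymmetric difference A - B feeds the cluster test.
    """
    a = np.atleast_2d(np.asarray(roi_r2_a, dtype=float))
    b = np.atleast_2d(np.asarray(roi_r2_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("subject/time mismatch between conditions")
    return a - b
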