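"""Cross-validated Mahalanobis (crossnobis) pattern dissimilarity.

The dissimilarity between the multichannel pattern evoked in the audio period
at time t_a and the pattern in the post-audio period at time t_v is estimated
across trials with independent train/test splits: the train-fold pattern
difference, whitened by the inverse train-fold noise covariance, is multiplied
with the test-fold difference.  Cross-validation makes the estimate unbiased
-- its expectation is zero when the two periods share a distribution, and it
may legitimately go negative -- so a decrease over learning is interpretable
as genuinely increased pattern similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import linalg
from sklearn.covariance import LedoitWolf
from sklearn.model_selection import KFold

from .epochs import EpochSet

__all__ = ["cvmd", "dissimilarity_matrix", "DissimilarityMatrix"]

AUDIO_WINDOW_MS = (200.0, 650.0)
POST_WINDOW_MS = (0.0, 550.0)


def cvmd(patterns_a: np.ndarray, patterns_p: np.ndarray, k_folds: int = 5,
         seed: Optional[int] = 0, folds=None) -> float:
    """Cross-validated Mahalanobis distance between two pattern sets.

    ``patterns_a`` and ``patterns_p`` are ``trials x channels`` responses of
    the *same* trials at two timepoints.  Per fold the train/test pattern
    differences are combined through the inverse Ledoit-Wolf covariance of the
    train residuals; fold estimates are averaged.
    """
    a = np.asarray(patterns_a, dtype=float)
    p = np.asarray(patterns_p, dtype=float)
    if a.shape != p.shape:
        raise ValueError("pattern sets must share trials and channels")
    n = a.shape[0]
    if folds is None:
        cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = list(cv.split(np.zeros(n)))
    vals = []
    for tr, te in folds:
        if tr.size < 2 or te.size < 1:
            raise ValueError("each fold needs at least 2 train and 1 test trial")
        m_a, m_p = a[tr].mean(axis=0), p[tr].mean(axis=0)
        d_train = m_a - m_p
        d_test = a[te].mean(axis=0) - p[te].mean(axis=0)
        resid = np.vstack([a[tr] - m_a, p[tr] - m_p])
        cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
        vals.append(float(d_train @ linalg.solve(cov, d_test, assume_a="pos")))
    return float(np.mean(vals))


@dataclass
class DissimilarityMatrix:
    """cvMD over an (audio time x post-audio time) grid for one trial set."""

    values: np.ndarray          # (n_audio_times, n_post_times)
    audio_times_ms: np.ndarray  # relative to auditory onset
    post_times_ms: np.ndarray   # relative to visual onset


def dissimilarity_matrix(
    epochs: EpochSet,
    trial_mask,
    roi_channels: Sequence[str],
    audio_window_ms: Tuple[float, float] = AUDIO_WINDOW_MS,
    post_window_ms: Tuple[float, float] = POST_WINDOW_MS,
    visual_onset_ms: float = 650.0,
    k_folds: int = 5,
    seed: Optional[int] = 0,
    step: int = 1,
) -> DissimilarityMatrix:
    """cvMD at every (audio time, post-audio time) grid point on ROI channels.

    ``post_window_ms`` is relative to the visual onset.  ``step`` decimates
    the sample grid (1 = every sample at the epoch rate).  One fold assignment
    is shared by all grid cells so cells are comparable.
    """
    sel = epochs.select(trial_mask)
    ch_idx = epochs.layout.index(roi_channels)
    a_idx = np.nonzero(epochs.time_mask(*audio_window_ms))[0][::step]
    p_idx = np.nonzero(epochs.time_mask(post_window_ms[0] + visual_onset_ms,
                                        post_window_ms[1] + visual_onset_ms))[0][::step]
    if a_idx.size == 0 or p_idx.size == 0:
        raise ValueError("analysis windows fall outside the epoch")
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros(sel.n_trials)))
    data = sel.data[:, ch_idx, :]
    values = np.empty((a_idx.size, p_idx.size))
    for i, ta in enumerate(a_idx):
        pa = data[:, :, ta]
        for j, tv in enumerate(p_idx):
            values[i, j] = cvmd(pa, data[:, :, tv], folds=folds)
    return DissimilarityMatrix(values=values,
                               audio_times_ms=epochs.times[a_idx],
                               post_times_ms=epochs.times[p_idx] - visual_onset_ms)
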