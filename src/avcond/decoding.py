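"""Time-resolved linear-discriminant decoding of the two tones.

At every timepoint, channel amplitudes across trials are the feature matrix of
a binary LDA with Ledoit-Wolf shrinkage of the class covariance, evaluated by
stratified 5-fold cross-validation with the area under the ROC curve of the
held-out discriminant scores.  Classifier weights are converted to
interpretable activation patterns by multiplication with the training-data
feature covariance (the activation-pattern, or Haufe, transform): a channel's
pattern value reflects how much class signal it carries, not how much the
classifier leans on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y

__all__ = ["DecodingResult", "TimeResolvedDecoder", "zscore_features",
           "decode_timecourse", "empirical_chance", "weights_to_patterns"]


def zscore_features(x: np.ndarray) -> np.ndarray:
    """Standardise each channel to mean 0, sd 1 across trials.

    Zero-variance channels are left at 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials to z-score")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s) left at 0")
        sd = np.where(zero, 1.0, sd)
    return (x - mean) / sd


def weights_to_patterns(weights: np.ndarray, covariance: np.ndarray
                        ) -> np.ndarray:
    """Activation pattern = training-data feature covariance @ weight vector."""
    return np.asarray(covariance, dtype=float) @ np.asarray(weights, dtype=float)


@dataclass
class DecodingResult:
    """Per-timepoint AUC, empirical-chance AUC, and activation patterns."""

    auc: np.ndarray                 # (n_times,)
    patterns: np.ndarray            # (n_channels, n_times), fold-averaged
    chance_auc: Optional[np.ndarray] = None


class TimeResolvedDecoder(BaseEstimator):
    """Per-timepoint shrinkage LDA with cross-validated AUC.

    Parameters
    ----------
    k_folds:
        Number of stratified cross-validation folds.
    shrinkage:
        Passed to :class:`~sklearn.discriminant_analysis.LinearDiscriminantAnalysis`
        with the ``lsqr`` solver; the default ``"auto"`` is Ledoit-Wolf.
    zscore:
        Standardise channels at each timepoint, with statistics estimated on
        the training folds only.
    random_state:
        Seed for fold shuffling.

    Attributes
    ----------
    auc_ : ndarray of shape (n_times,)
        Fold-averaged held-out AUC per timepoint.
    patterns_ : ndarray of shape (n_channels, n_times)
        Fold-averaged activation patterns.
    """

    def __init__(self, k_folds: int = 5, shrinkage: str = "auto",
                 zscore: bool = True, random_state: Optional[int] = None):
        self.k_folds = k_folds
        self.shrinkage = shrinkage
        self.zscore = zscore
        self.random_state = random_state

    def fit(self, X: np.ndarray, y) -> "TimeResolvedDecoder":
        """Cross-validate on ``X`` (trials x channels x times), labels ``y``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be trials x channels x times")
        y = np.asarray(y)
        check_X_y(X.reshape(X.shape[0], -1), y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        counts = np.bincount(y_enc)
        if counts.min() < self.k_folds:
            raise ValueError("each class needs at least k_folds trials")

        n_trials, n_ch, n_times = X.shape
        cv = StratifiedKFold(n_splits=self.k_folds, shuffle=True,
                             random_state=self.random_state)
        folds = list(cv.split(np.zeros(n_trials), y_enc))
        auc = np.zeros((self.k_folds, n_times))
        patterns = np.zeros((self.k_folds, n_ch, n_times))
        for t in range(n_times):
            Xt = X[:, :, t]
            for f, (tr, te) in enumerate(folds):
                x_tr, x_te = Xt[tr], Xt[te]
                if self.zscore:
                    mean = x_tr.mean(axis=0)
                    sd = x_tr.std(axis=0, ddof=0)
                    sd[sd == 0] = 1.0
                    x_tr = (x_tr - mean) / sd
                    x_te = (x_te - mean) / sd
                lda = LinearDiscriminantAnalysis(solver="lsqr",
                                                 shrinkage=self.shrinkage)
                lda.fit(x_tr, y_enc[tr])
                scores = lda.decision_function(x_te)
                auc[f, t] = roc_auc_score(y_enc[te], scores)
                cov = np.cov(x_tr, rowvar=False)
                patterns[f, :, t] = weights_to_patterns(lda.coef_.ravel(), cov)
        self.classes_ = classes
        self.auc_ = auc.mean(axis=0)
        self.auc_folds_ = auc
        self.patterns_ = patterns.mean(axis=0)
        return self

    def score(self, X=None, y=None) -> float:
        """Mean cross-validated AUC over timepoints (from the last fit)."""
        return float(self.auc_.mean())


def decode_timecourse(epochs_data: np.ndarray, labels, k_folds: int = 5,
                      seed: Optional[int] = 0) -> DecodingResult:
    """Functional wrapper over `TimeResolvedDecoder`."""
    dec = TimeResolvedDecoder(k_folds=k_folds, random_state=seed)
    dec.fit(epochs_data, labels)
    return DecodingResult(auc=dec.auc_, patterns=dec.patterns_)


def empirical_chance(epochs_data: np.ndarray, labels, k_folds: int = 5,
                     n_runs: int = 2, seed: Optional[int] = 0) -> np.ndarray:
    """Chance AUC time course from label-permuted re-runs, averaged."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    runs = []
    for _ in range(n_runs):
        perm = rng.permutation(labels.size)
        run_seed = int(rng.integers(2**31 - 1))
        runs.append(decode_timecourse(epochs_data, labels[perm],
                                      k_folds=k_folds, seed=run_seed).auc)
    return np.mean(runs, axis=0)
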