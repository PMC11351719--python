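"""Group-level paired permutation tests with cluster correction.

Subject-wise difference maps (1-D time courses or 2-D time-by-time grids) are
tested against zero: per point a paired t statistic, cluster forming at the
two-tailed t critical value, the maxsum (summed t within a cluster) as the
cluster statistic, and a sign-flip permutation null of the maximum absolute
maxsum for family-wise correction.  Effect sizes (Cohen's d and the JZS Bayes
factor with a Cauchy prior on the standardised effect) are reported at each
cluster's peak-|t| point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import integrate, ndimage
from scipy import stats as sps

__all__ = ["Cluster", "ClusterResult", "paired_cluster_test", "cohens_d",
           "jzs_bf10"]


def cohens_d(diffs) -> float:
    """Paired-sample effect size: mean / sd (n-1 denominator)."""
    x = np.asarray(diffs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: d undefined")
    return float(x.mean() / sd)


def jzs_bf10(diffs, cauchy_scale: float = np.sqrt(2.0) / 2.0) -> float:
    """One-sample JZS Bayes factor (alternative over point null).

    The marginal likelihood under the alternative integrates the noncentral-t
    density of the observed t statistic over a Cauchy prior (scale
    ``cauchy_scale``) on the standardised effect size delta, with
    noncentrality delta * sqrt(n); the null likelihood is the central-t
    density.
    """
    x = np.asarray(diffs, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    t = float(x.mean() / (x.std(ddof=1) / np.sqrt(n)))
    df = n - 1

    def integrand(delta):
        return (sps.nct.pdf(t, df, delta * np.sqrt(n))
                * sps.cauchy.pdf(delta, scale=cauchy_scale))

    # the noncentral-t factor concentrates near delta = t / sqrt(n); split the
    # axis there so quadrature cannot miss a narrow peak at large |t|
    d_hat = t / np.sqrt(n)
    width = 12.0 * (1.0 + abs(t) / np.sqrt(df)) / np.sqrt(n)
    knots = sorted({-np.inf, min(0.0, d_hat - width), d_hat - width,
                    d_hat + width, max(0.0, d_hat + width), np.inf})
    m1, err = 0.0, 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        if lo == hi:
            continue
        val, e = integrate.quad(integrand, lo, hi, limit=200)
        m1 += val
        err += e
    m0 = sps.t.pdf(t, df)
    if not np.isfinite(m1) or m1 <= 0 or err > 1e-4 * m1:
        raise RuntimeError("Bayes factor integration failed")
    return float(m1 / m0)


@dataclass
class Cluster:
    """One supra-threshold cluster with its statistics."""

    indices: np.ndarray       # member points (flat indices into the map)
    maxsum: float             # summed t over members
    p_corrected: float
    sign: int                 # +1 positive cluster, -1 negative
    peak_index: int           # flat index of max |t| inside the cluster
    peak_t: float
    peak_d: float
    peak_bf10: float

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(), "maxsum": self.maxsum,
            "p_corrected": self.p_corrected, "sign": self.sign,
            "peak_index": self.peak_index, "peak_t": self.peak_t,
            "peak_d": self.peak_d, "peak_bf10": self.peak_bf10,
        }


@dataclass
class ClusterResult:
    """All clusters of one map plus the pointwise t map and null quantile."""

    clusters: List[Cluster]
    t_map: np.ndarray
    threshold: float
    n_perm: int
    shape: tuple

    def significant(self, alpha: float = 0.05) -> List[Cluster]:
        return [c for c in self.clusters if c.p_corrected <= alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros(self.t_map.size, dtype=bool)
        for c in self.significant(alpha):
            mask[c.indices] = True
        return mask.reshape(self.shape)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "n_perm": self.n_perm,
                "shape": list(self.shape),
                "clusters": [c.to_dict() for c in self.clusters]}

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _t_map(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _clusters_and_sums(t: np.ndarray, thr: float, structure) -> list:
    """[(member flat indices, summed t), ...] for both signs."""
    out = []
    for sign in (1, -1):
        mask = sign * t > thr
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            members = np.nonzero(labels.ravel() == lab)[0]
            out.append((members, float(t.ravel()[members].sum())))
    return out


def paired_cluster_test(
    diffs: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: Optional[int] = 0,
    cauchy_scale: float = np.sqrt(2.0) / 2.0,
    block: int = 256,
) -> ClusterResult:
    """Sign-flip cluster permutation test of paired differences against zero.

    Parameters
    ----------
    diffs:
        ``subjects x points`` (1-D maps) or ``subjects x rows x cols``
        (2-D maps, clustered with 4-connectivity).
    n_perm:
        Number of random sign-flip permutations for the null of the maximum
        absolute cluster maxsum.  Corrected p-values are
        ``(1 + #{null >= observed}) / (n_perm + 1)`` and can never be 0.
    alpha:
        Two-tailed cluster-forming level: points with ``|t|`` above the
        t critical value at ``alpha`` enter clusters.
    """
    x = np.asarray(diffs, dtype=float)
    if x.ndim not in (2, 3):
        raise ValueError("diffs must be subjects x points or subjects x rows x cols")
    n_subj = x.shape[0]
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    map_shape = x.shape[1:]
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("zero-variance differences at every point")
    structure = None if x.ndim == 2 else ndimage.generate_binary_structure(2, 1)

    t_obs = _t_map(x)
    thr = float(sps.t.ppf(1.0 - alpha / 2.0, n_subj - 1))
    observed = _clusters_and_sums(t_obs, thr, structure)

    # permutation null of max |maxsum|; t maps for whole sign-flip blocks are
    # computed by matrix algebra (sign flips leave sum(x^2) unchanged)
    rng = np.random.default_rng(seed)
    flat = x.reshape(n_subj, -1)
    ss = np.einsum("sp,sp->p", flat, flat)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n_subj))
        means = signs @ flat / n_subj
        var = (ss[None, :] - n_subj * means ** 2) / (n_subj - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = means / np.sqrt(var / n_subj)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)
        for i in range(k):
            sums = [abs(s) for _, s in
                    _clusters_and_sums(t_perm[i].reshape(map_shape), thr, structure)]
            null_max[done + i] = max(sums) if sums else 0.0
        done += k

    clusters = []
    for members, csum in observed:
        p = float((1 + np.sum(null_max >= abs(csum))) / (n_perm + 1))
        t_flat = t_obs.ravel()
        peak = int(members[np.argmax(np.abs(t_flat[members]))])
        peak_diffs = flat[:, peak]
        clusters.append(Cluster(
            indices=members, maxsum=csum, p_corrected=p,
            sign=1 if csum > 0 else -1, peak_index=peak,
            peak_t=float(t_flat[peak]), peak_d=cohens_d(peak_diffs),
            peak_bf10=jzs_bf10(peak_diffs, cauchy_scale=cauchy_scale),
        ))
    clusters.sort(key=lambda c: abs(c.maxsum), reverse=True)
    return ClusterResult(clusters=clusters, t_map=t_obs, threshold=thr,
                         n_perm=n_perm, shape=map_shape)
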