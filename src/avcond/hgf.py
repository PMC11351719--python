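"""Three-level binary Hierarchical Gaussian Filter (HGF).

Generative model: a slowly drifting log-volatility x3 (Gaussian random walk,
step variance theta) sets the step variance exp(kappa * x3 + omega) of a
log-odds tendency x2, which generates binary outcomes x1 ~ Bernoulli(s(x2))
through the logistic sigmoid s.  Inverting the model trial by trial yields,
at each level, posterior means that move by a precision-weighted prediction
error; the level-2 increment

    mu2[t] = mu2[t-1] + sigma2[t] * (u[t] - s(mu2[t-1]))

is the pwPE trajectory used as a single-trial EEG regressor.  Bayes-optimal
parameters for a given input sequence minimise the accumulated Bayesian
surprise (negative log predictive probability) plus a Gaussian prior penalty,
via quasi-Newton (BFGS) optimisation started at the prior means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["HgfParams", "HgfTrajectory", "HgfUnstableError", "sigmoid",
           "hgf_simulate", "hgf_filter", "bayesian_surprise",
           "BayesOptimalHgf", "bayes_optimal_fit", "pwpe_per_condition"]


class HgfUnstableError(RuntimeError):
    """Raised when a parameter set yields a non-positive posterior precision."""


def sigmoid(x):
    """Numerically stable logistic sigmoid 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass
class HgfParams:
    """HGF parameters and initial beliefs.

    kappa couples the third level to the second's volatility; omega is the
    tonic log-volatility of the second level; theta is the step variance of
    the third level's random walk.
    """

    kappa: float = 1.0
    omega: float = -3.0
    theta: float = 0.005
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be > 0")


@dataclass
class HgfTrajectory:
    """Per-trial beliefs, precisions, prediction errors and pwPEs."""

    u: np.ndarray        # binary inputs
    muhat1: np.ndarray   # predicted outcome probability s(mu2 prior)
    muhat2: np.ndarray
    muhat3: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    sigma2: np.ndarray   # posterior level-2 variance
    sigma3: np.ndarray
    delta0: np.ndarray   # outcome prediction error u - muhat1
    delta2: np.ndarray   # volatility prediction error feeding level 3
    epsilon2: np.ndarray  # level-2 pwPE: sigma2 * delta0
    epsilon3: np.ndarray  # level-3 belief increment
    params: HgfParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "u": self.u, "muhat1": self.muhat1, "muhat2": self.muhat2,
            "muhat3": self.muhat3, "mu2": self.mu2, "mu3": self.mu3,
            "sigma2": self.sigma2, "sigma3": self.sigma3,
            "delta0": self.delta0, "delta2": self.delta2,
            "epsilon2": self.epsilon2, "epsilon3": self.epsilon3,
        })


def hgf_simulate(params: HgfParams, n_trials: int, seed: Optional[int] = 0
                 ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample latent random walks and binary outcomes from the generative model.

    Returns (latent-state DataFrame with columns x1, x2, x3; input sequence u).
    """
    rng = np.random.default_rng(seed)
    x2 = np.empty(n_trials)
    x3 = np.empty(n_trials)
    x1 = np.empty(n_trials, dtype=int)
    prev2, prev3 = params.mu2_0, params.mu3_0
    for t in range(n_trials):
        x3[t] = rng.normal(prev3, np.sqrt(params.theta))
        step_var = np.exp(params.kappa * x3[t] + params.omega)
        x2[t] = rng.normal(prev2, np.sqrt(step_var))
        x1[t] = int(rng.random() < sigmoid(x2[t]))
        prev2, prev3 = x2[t], x3[t]
    states = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    return states, x1.astype(float)


def hgf_filter(u, params: HgfParams) -> HgfTrajectory:
    """Trial-wise variational belief updates for a binary input sequence.

    At each trial the level-1 prediction is s(mu2 prior); the level-2
    posterior precision adds the Bernoulli observation precision
    muhat1 * (1 - muhat1) to the prediction precision, and the mean moves by
    sigma2 * (u - muhat1).  Level 3 is updated with the volatility prediction
    error, weighted by its posterior variance and the volatility weight w2.
    Raises `HgfUnstableError` if the level-3 posterior precision turns
    non-positive (model misfit for this parameter set).
    """
    u = np.asarray(u, dtype=float)
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("inputs must be binary 0/1")
    n = u.size
    ka, om, th = params.kappa, params.omega, params.theta
    mu2, sigma2 = params.mu2_0, params.sigma2_0
    mu3, sigma3 = params.mu3_0, params.sigma3_0

    cols = {k: np.empty(n) for k in ("muhat1", "muhat2", "muhat3", "mu2", "mu3",
                                     "sigma2", "sigma3", "delta0", "delta2",
                                     "epsilon2", "epsilon3")}
    for t in range(n):
        v2 = np.exp(ka * mu3 + om)            # predicted level-2 step variance
        sigma2hat = sigma2 + v2
        pihat2 = 1.0 / sigma2hat
        muhat2 = mu2
        muhat1 = sigmoid(muhat2)
        delta0 = u[t] - muhat1

        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        sigma2_new = 1.0 / pi2
        eps2 = sigma2_new * delta0
        mu2_new = muhat2 + eps2               # the level-2 pwPE update

        pihat3 = 1.0 / (sigma3 + th)
        w2 = v2 / sigma2hat
        delta2 = (sigma2_new + (mu2_new - muhat2) ** 2) / sigma2hat - 1.0
        pi3 = pihat3 + 0.5 * ka ** 2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0 or not np.isfinite(pi3):
            raise HgfUnstableError(
                f"non-positive level-3 posterior precision at trial {t}")
        sigma3_new = 1.0 / pi3
        eps3 = sigma3_new * 0.5 * ka * w2 * delta2
        mu3_new = mu3 + eps3

        cols["muhat1"][t] = muhat1
        cols["muhat2"][t] = muhat2
        cols["muhat3"][t] = mu3
        cols["mu2"][t] = mu2_new
        cols["mu3"][t] = mu3_new
        cols["sigma2"][t] = sigma2_new
        cols["sigma3"][t] = sigma3_new
        cols["delta0"][t] = delta0
        cols["delta2"][t] = delta2
        cols["epsilon2"][t] = eps2
        cols["epsilon3"][t] = eps3
        mu2, sigma2, mu3, sigma3 = mu2_new, sigma2_new, mu3_new, sigma3_new

    return HgfTrajectory(u=u, params=params, **cols)


def bayesian_surprise(u, params: HgfParams) -> float:
    """Accumulated negative log predictive probability of the input sequence."""
    traj = hgf_filter(u, params)
    p = np.clip(traj.muhat1, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(np.log(np.where(traj.u == 1, p, 1.0 - p))))


class BayesOptimalHgf:
    """Bayes-optimal inversion of the perceptual model for an input sequence.

    Minimises Bayesian surprise plus a Gaussian prior penalty over
    (omega, log theta) -- and log kappa when ``estimate_kappa`` -- by BFGS
    from the prior means.  Priors default to wide Gaussians; kappa is fixed
    at 1 unless estimated.

    Attributes (after ``fit``)
    --------------------------
    params_ : HgfParams           fitted parameters
    trajectory_ : HgfTrajectory   filter run at the fitted parameters
    surprise_ : float             Bayesian surprise at the optimum
    objective_ : float            penalised objective at the optimum
    converged_ : bool             optimiser convergence flag
    """

    _BAD = 1e8  # objective for unstable / non-finite parameter sets

    def __init__(self,
                 prior_omega: Tuple[float, float] = (-3.0, 16.0),
                 prior_log_theta: Tuple[float, float] = (-6.0, 16.0),
                 prior_log_kappa: Tuple[float, float] = (0.0, 1.0),
                 estimate_kappa: bool = False,
                 init: Optional[HgfParams] = None,
                 max_iter: int = 200):
        self.prior_omega = prior_omega
        self.prior_log_theta = prior_log_theta
        self.prior_log_kappa = prior_log_kappa
        self.estimate_kappa = estimate_kappa
        self.init = init
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> Dict:
        return {k: getattr(self, k) for k in
                ("prior_omega", "prior_log_theta", "prior_log_kappa",
                 "estimate_kappa", "init", "max_iter")}

    def set_params(self, **kwargs) -> "BayesOptimalHgf":
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def _unpack(self, x: np.ndarray) -> HgfParams:
        base = self.init or HgfParams()
        kw = dict(omega=float(x[0]), theta=float(np.exp(x[1])))
        if self.estimate_kappa:
            kw["kappa"] = float(np.exp(x[2]))
        return replace(base, **kw)

    def _objective(self, x: np.ndarray, u: np.ndarray) -> float:
        if not np.all(np.isfinite(x)) or x[1] > 10:
            return self._BAD
        try:
            params = self._unpack(x)
            nll = bayesian_surprise(u, params)
        except (HgfUnstableError, FloatingPointError, OverflowError, ValueError):
            return self._BAD
        if not np.isfinite(nll):
            return self._BAD
        priors = [self.prior_omega, self.prior_log_theta]
        if self.estimate_kappa:
            priors.append(self.prior_log_kappa)
        pen = sum((xi - m) ** 2 / (2.0 * v) for xi, (m, v) in zip(x, priors))
        return nll + pen

    def fit(self, u) -> "BayesOptimalHgf":
        u = np.asarray(u, dtype=float)
        if u.size < 20:
            raise ValueError("need at least 20 trials to fit")
        x0 = [self.prior_omega[0], self.prior_log_theta[0]]
        if self.estimate_kappa:
            x0.append(self.prior_log_kappa[0])
        x0 = np.asarray(x0, dtype=float)
        res = optimize.minimize(self._objective, x0, args=(u,), method="BFGS",
                                options={"maxiter": self.max_iter})
        # the optimiser only ever moves downhill from the prior means, but
        # guard against a pathological line-search ending above the start
        x_best = res.x if res.fun <= self._objective(x0, u) else x0
        self.params_ = self._unpack(x_best)
        self.trajectory_ = hgf_filter(u, self.params_)
        self.surprise_ = bayesian_surprise(u, self.params_)
        self.objective_ = float(min(res.fun, self._objective(x0, u)))
        self.converged_ = bool(res.success)
        return self


def bayes_optimal_fit(u, **kwargs) -> Tuple[HgfParams, BayesOptimalHgf]:
    """Fit Bayes-optimal parameters; returns (params, fitted estimator)."""
    est = BayesOptimalHgf(**kwargs).fit(u)
    return est.params_, est


def pwpe_per_condition(schedule: pd.DataFrame, absolute: bool = True,
                       **fit_kwargs) -> Dict[str, pd.DataFrame]:
    """Level-2 pwPE trajectories for each auditory condition of a schedule.

    For each condition the input sequence is u = 1 iff the visual stimulus
    occurred on that trial; a separate Bayes-optimal model is fitted per
    condition.  Returns ``{condition: DataFrame(trial_id, u, pwpe)}`` with
    ``pwpe`` the (absolute, by default) level-2 pwPE aligned to trial ids.
    """
    out = {}
    for cond, vis in (("A1", "V1"), ("A2", "V2")):
        rows = schedule[schedule["trial_type"] == f"{cond}-trial"]
        if len(rows) < 20:
            raise ValueError(f"condition {cond} has fewer than 20 trials")
        u = (rows["visual_outcome"] == vis).to_numpy(dtype=float)
        _, est = bayes_optimal_fit(u, **fit_kwargs)
        eps2 = est.trajectory_.epsilon2
        out[cond] = pd.DataFrame({
            "trial_id": rows["trial_id"].to_numpy(),
            "u": u,
            "pwpe": np.abs(eps2) if absolute else eps2,
        })
    return out
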