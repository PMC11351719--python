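"""Independent reference implementations used only as test oracles."""

import numpy as np

from avcond.hgf import HgfParams, sigmoid


def grid_filter_muhat1(u, p: HgfParams, n2: int = 161, n3: int = 81,
                       span2: float = 8.0, span3: float = 4.0) -> np.ndarray:
    """Exact Bayesian filtering of the 3-level binary model on a dense grid.

    The joint density over (x2, x3) is propagated numerically through the
    Gaussian random-walk transitions and updated with the Bernoulli
    likelihood; returns the predictive outcome probability per trial.
    """
    x2 = np.linspace(p.mu2_0 - span2, p.mu2_0 + span2, n2)
    x3 = np.linspace(p.mu3_0 - span3, p.mu3_0 + span3, n3)
    joint = np.outer(np.exp(-0.5 * (x2 - p.mu2_0) ** 2 / p.sigma2_0),
                     np.exp(-0.5 * (x3 - p.mu3_0) ** 2 / p.sigma3_0))
    joint /= joint.sum()
    k3 = np.exp(-0.5 * (x3[None, :] - x3[:, None]) ** 2 / p.theta)
    k3 /= k3.sum(axis=1, keepdims=True)
    k2 = np.empty((n3, n2, n2))
    for j in range(n3):
        var = np.exp(p.kappa * x3[j] + p.omega)
        k = np.exp(-0.5 * (x2[None, :] - x2[:, None]) ** 2 / var)
        k2[j] = k / k.sum(axis=1, keepdims=True)
    s = sigmoid(x2)
    preds = []
    for ut in np.asarray(u, dtype=float):
        q = joint @ k3                              # (x2, x3')
        prior = np.einsum("jab,aj->bj", k2, q)      # propagate x2 given x3'
        prior /= prior.sum()
        preds.append(float((s[:, None] * prior).sum()))
        lik = s if ut == 1 else 1.0 - s
        joint = prior * lik[:, None]
        joint /= joint.sum()
    return np.array(preds)


def naive_cvmd(a: np.ndarray, p: np.ndarray, folds) -> float:
    """Fold-by-fold brute-force crossnobis distance (explicit loops)."""
    from sklearn.covariance import LedoitWolf

    vals = []
    for train, test in folds:
        m_a = a[train].mean(axis=0)
        m_p = p[train].mean(axis=0)
        d_train = m_a - m_p
        d_test = a[test].mean(axis=0) - p[test].mean(axis=0)
        resid = np.concatenate([a[train] - m_a, p[train] - m_p], axis=0)
        cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
        vals.append(d_train @ np.linalg.inv(cov) @ d_test)
    return float(np.mean(vals))


def lda_rank_auc(x_train, y_train, x_test, y_test) -> float:
    """Closed-form LDA discriminant + Mann-Whitney rank AUC.

    w = Sigma^-1 (m1 - m0) with the pooled (class-size weighted, ddof=0)
    within-class covariance; AUC is the normalised Mann-Whitney U statistic
    of the test-set discriminant scores.
    """
    from scipy.stats import mannwhitneyu

    x0, x1 = x_train[y_train == 0], x_train[y_train == 1]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    s0 = (x0 - m0).T @ (x0 - m0)
    s1 = (x1 - m1).T @ (x1 - m1)
    cov = (s0 + s1) / x_train.shape[0]
    w = np.linalg.solve(cov, m1 - m0)
    scores = x_test @ w
    u_stat = mannwhitneyu(scores[y_test == 1], scores[y_test == 0],
                          alternative="two-sided").statistic
    return float(u_stat / ((y_test == 1).sum() * (y_test == 0).sum()))


def jzs_bf10_gquad(diffs, r: float = np.sqrt(2.0) / 2.0) -> float:
    """JZS Bayes factor via the g-prior integral (independent route).

    Integrates the marginal likelihood over g with the inverse-gamma(1/2,
    r^2/2) prior implied by a Cauchy(0, r) prior on the effect size.
    """
    from scipy import integrate
    from scipy.special import gammaln

    x = np.asarray(diffs, dtype=float)
    n = x.size
    t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
    nu = n - 1

    def integrand(g):
        lik = (1 + n * g) ** -0.5 * (1 + t ** 2 / ((1 + n * g) * nu)) ** (
            -(nu + 1) / 2.0)
        prior = ((r ** 2 / 2.0) ** 0.5 / np.exp(gammaln(0.5))
                 * g ** -1.5 * np.exp(-r ** 2 / (2.0 * g)))
        return lik * prior

    num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    den = (1 + t ** 2 / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)
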