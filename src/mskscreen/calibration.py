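"""Semi-analytic moments of the latent-severity cohort model.

These quadrature routines compute, without simulation, the quantities the
generator presets were calibrated against: the 0-8 score's mean/SD and
floor/ceiling probabilities, the poor-outcome prevalence, and the exact
population AUC of the score against the poor-outcome flag.  They serve
two purposes: (1) the preset constants in :mod:`mskscreen.simulate` were
fitted against these expressions; (2) tests use them as an independent
oracle for the Monte-Carlo generator.

All integrals over the latent severity theta ~ N(0,1) use Gauss-Hermite
quadrature (probabilists' convention).  Clipping of the PCS to [0, 100]
never moves a value across the poor-outcome threshold (33), so prevalence
and AUC computed here are exact for the clipped model as well; the PCS
mean/SD are computed for the unclipped Gaussian and are approximations
when clipping is material.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .scoring import N_ITEMS, POOR_OUTCOME_PCS_MAX
from .simulate import SyntheticConfig

_N_QUAD = 80


def _gh_nodes(n: int = _N_QUAD) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(theta)], theta ~ N(0,1)."""
    x, w = special.roots_hermitenorm(n)
    return x, w / np.sqrt(2.0 * np.pi)


def _item_probs(alpha, beta, theta: np.ndarray) -> np.ndarray:
    """(n_nodes, 8) conditional positive-response probabilities."""
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    return special.expit(a[None, :] + np.outer(theta, b))


def score_pmf_given_theta(alpha, beta, theta: np.ndarray) -> np.ndarray:
    """Poisson-binomial pmf of the 0-8 score at each theta node: (n, 9)."""
    p = _item_probs(alpha, beta, theta)
    pmf = np.zeros((p.shape[0], N_ITEMS + 1))
    pmf[:, 0] = 1.0
    for i in range(N_ITEMS):
        pi = p[:, i : i + 1]
        shifted = np.zeros_like(pmf)
        shifted[:, 1:] = pmf[:, :-1]
        pmf = pmf * (1.0 - pi) + shifted * pi
    return pmf


def score_distribution(alpha, beta) -> np.ndarray:
    """Marginal pmf of the score over theta ~ N(0,1)."""
    theta, w = _gh_nodes()
    pmf = score_pmf_given_theta(alpha, beta, theta)
    return w @ pmf


def score_moments(alpha, beta) -> tuple[float, float]:
    """Population mean and SD of the 0-8 score."""
    pmf = score_distribution(alpha, beta)
    s = np.arange(N_ITEMS + 1)
    mean = float(pmf @ s)
    var = float(pmf @ s**2 - mean**2)
    return mean, float(np.sqrt(var))


def floor_ceiling_probs(alpha, beta) -> tuple[float, float]:
    """P(score = 0) and P(score = 8)."""
    pmf = score_distribution(alpha, beta)
    return float(pmf[0]), float(pmf[-1])


def _poor_prob_given_theta(gamma: float, mu: float, sigma: float, theta: np.ndarray) -> np.ndarray:
    # pcs <= 33  <=>  eps <= 33 - mu + gamma*theta  (clipping cannot cross 33)
    return stats.norm.cdf((POOR_OUTCOME_PCS_MAX - mu + gamma * theta) / sigma)


def poor_prevalence(config: SyntheticConfig) -> float:
    """Marginal P(poor outcome) under the config's region mixture."""
    theta, w = _gh_nodes()
    prev = 0.0
    for region, pi in config.region_mix.items():
        prev += pi * float(w @ _poor_prob_given_theta(
            config.gamma[region], config.pcs_mu, config.pcs_sigma, theta
        ))
    return prev


def true_auc(config: SyntheticConfig, region: str) -> float:
    """Exact population AUC of score vs poor outcome within one region.

    Joint pmf of (score, outcome) by quadrature, then the Mann-Whitney
    functional with 0.5 credit for ties.
    """
    theta, w = _gh_nodes()
    pmf = score_pmf_given_theta(config.alpha, config.beta, theta)
    q = _poor_prob_given_theta(config.gamma[region], config.pcs_mu, config.pcs_sigma, theta)
    f_case = (w * q) @ pmf        # unnormalised P(S = s, poor)
    f_ctrl = (w * (1.0 - q)) @ pmf
    p1, p0 = f_case.sum(), f_ctrl.sum()
    if p1 <= 0 or p0 <= 0:
        raise ValueError("degenerate outcome distribution for this region")
    f_case, f_ctrl = f_case / p1, f_ctrl / p0
    cdf_ctrl = np.cumsum(f_ctrl)
    below = np.concatenate([[0.0], cdf_ctrl[:-1]])  # P(control score < s)
    return float(np.sum(f_case * (below + 0.5 * f_ctrl)))


def true_auc_pooled(config: SyntheticConfig) -> float:
    """Population AUC pooling all regions (mixture over gamma)."""
    theta, w = _gh_nodes()
    pmf = score_pmf_given_theta(config.alpha, config.beta, theta)
    f_case = np.zeros(N_ITEMS + 1)
    f_ctrl = np.zeros(N_ITEMS + 1)
    for region, pi in config.region_mix.items():
        q = _poor_prob_given_theta(config.gamma[region], config.pcs_mu, config.pcs_sigma, theta)
        f_case += pi * ((w * q) @ pmf)
        f_ctrl += pi * ((w * (1.0 - q)) @ pmf)
    f_case /= f_case.sum()
    f_ctrl /= f_ctrl.sum()
    cdf_ctrl = np.cumsum(f_ctrl)
    below = np.concatenate([[0.0], cdf_ctrl[:-1]])
    return float(np.sum(f_case * (below + 0.5 * f_ctrl)))
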