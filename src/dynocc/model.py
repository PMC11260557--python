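"""Marginalized dynamic-occupancy likelihood and Bayesian inference.

The data model is the classic multi-season (dynamic) occupancy model:
each site i carries a latent binary occupancy state z[i, t] per primary
period t, initialized by psi1_i, evolving by colonization gamma[i, t]
(0 -> 1) and extirpation epsilon[i, t] (1 -> 0), and observed through
imperfect weekly detections y[i, t, j] ~ Bernoulli(p_i) when occupied
(false positives are assumed impossible, so any detection forces
z = 1).  All four probabilities sit on logit-linear predictors built by
:mod:`dynocc.design`; detection additionally carries a site-level
random intercept eta_i ~ normal(0, sigma_eta) absorbing unmodelled
heterogeneity (lure placement, camera angle, microhabitat).

Rather than sampling the latent z (the usual data-augmentation route),
the likelihood marginalizes z with the two-state hidden-Markov forward
algorithm.  This keeps the parameter space continuous, admits exact
gradients via the forward-backward recursions, and is directly
testable against brute-force enumeration over latent sequences.

Priors: independent normal(0, 2.5) on all standardized-scale
coefficients, half-normal(0, 1) on sigma_eta, and a non-centred
normal(0, 1) parameterization of the site effects
(eta_i = sigma_eta * eta_raw_i).  sigma_eta is sampled on the log
scale with the Jacobian included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .design import DesignBlocks, P_COLUMNS, PSI1_COLUMNS, TRANSITION_COLUMNS

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamLayout:
    """Index map of the flat sampled vector.

    Order: beta_psi1 (4), beta_p (3), beta_gamma (10), beta_epsilon (10),
    log_sigma_eta (1), eta_raw (n_sites).
    """

    n_sites: int

    @property
    def dim(self) -> int:
        return 4 + 3 + 10 + 10 + 1 + self.n_sites

    @property
    def slices(self) -> dict[str, slice]:
        return {
            "beta_psi1": slice(0, 4),
            "beta_p": slice(4, 7),
            "beta_gamma": slice(7, 17),
            "beta_epsilon": slice(17, 27),
            "log_sigma_eta": slice(27, 28),
            "eta_raw": slice(28, 28 + self.n_sites),
        }

    @property
    def names(self) -> list[str]:
        out = [f"psi1_{c}" for c in PSI1_COLUMNS]
        out += [f"p_{c}" for c in P_COLUMNS]
        out += [f"gamma_{c}" for c in TRANSITION_COLUMNS]
        out += [f"epsilon_{c}" for c in TRANSITION_COLUMNS]
        out += ["log_sigma_eta"]
        out += [f"eta_raw[{i}]" for i in range(self.n_sites)]
        return out

    @property
    def structural_names(self) -> list[str]:
        """Coefficients plus sigma_eta — the reported parameters."""
        return self.names[:27] + ["log_sigma_eta"]


@dataclass
class Params:
    """Unpacked model parameters (natural scale for sigma_eta)."""

    beta_psi1: np.ndarray
    beta_p: np.ndarray
    beta_gamma: np.ndarray
    beta_epsilon: np.ndarray
    sigma_eta: float = 0.5
    eta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def pack(self, layout: ParamLayout) -> np.ndarray:
        theta = np.zeros(layout.dim)
        s = layout.slices
        theta[s["beta_psi1"]] = self.beta_psi1
        theta[s["beta_p"]] = self.beta_p
        theta[s["beta_gamma"]] = self.beta_gamma
        theta[s["beta_epsilon"]] = self.beta_epsilon
        theta[s["log_sigma_eta"]] = np.log(self.sigma_eta)
        eta = self.eta if self.eta.size else np.zeros(layout.n_sites)
        theta[s["eta_raw"]] = eta / self.sigma_eta
        return theta

    @classmethod
    def unpack(cls, theta: np.ndarray, layout: ParamLayout) -> "Params":
        s = layout.slices
        sigma = float(np.exp(theta[s["log_sigma_eta"]][0]))
        return cls(
            beta_psi1=theta[s["beta_psi1"]].copy(),
            beta_p=theta[s["beta_p"]].copy(),
            beta_gamma=theta[s["beta_gamma"]].copy(),
            beta_epsilon=theta[s["beta_epsilon"]].copy(),
            sigma_eta=sigma,
            eta=sigma * theta[s["eta_raw"]].copy(),
        )


# ---------------------------------------------------------------------------
# reference single-site likelihood (general per-occasion p)
# ---------------------------------------------------------------------------

def site_loglik(y, psi1: float, gamma, epsilon, p) -> float:
    """Log-likelihood of one site's detection history, latent state
    marginalized by the forward algorithm.

    Parameters
    ----------
    y : array (T, J)
        0/1 detections with NaN for missing occasions.
    psi1 : float
        Initial occupancy probability.
    gamma, epsilon : array (T-1,)
        Colonization and extirpation probabilities per transition.
    p : float or array broadcastable to (T, J)
        Per-occasion detection probability given occupancy.

    A detection at a site the model deems unoccupiable has probability
    zero; the function then returns ``-inf`` rather than raising.
    """
    y = np.atleast_2d(np.asarray(y, float))
    T, J = y.shape
    p = np.clip(np.broadcast_to(np.asarray(p, float), y.shape), _PCLIP, 1 - _PCLIP)
    gamma = np.asarray(gamma, float).reshape(-1)
    epsilon = np.asarray(epsilon, float).reshape(-1)
    if gamma.size != T - 1 or epsilon.size != T - 1:
        raise ValueError("gamma and epsilon must have length T-1")

    obs = ~np.isnan(y)
    yv = np.nan_to_num(y)
    with np.errstate(divide="ignore"):
        logE1 = np.where(obs, yv * np.log(p) + (1 - yv) * np.log1p(-p), 0.0).sum(axis=1)
    any_det = (yv * obs).sum(axis=1) > 0
    E0 = np.where(any_det, 0.0, 1.0)

    # scaled forward recursion; emissions for z=1 shifted by their own max
    shift = np.where(any_det, logE1, np.maximum(logE1, 0.0))
    E1 = np.exp(logE1 - shift)
    E0 = E0 * np.exp(-shift)

    a0 = (1.0 - psi1) * E0[0]
    a1 = psi1 * E1[0]
    loglik = shift.sum()
    for t in range(T):
        if t > 0:
            g, e = gamma[t - 1], epsilon[t - 1]
            pr0 = a0 * (1 - g) + a1 * e
            pr1 = a0 * g + a1 * (1 - e)
            a0, a1 = pr0 * E0[t], pr1 * E1[t]
        c = a0 + a1
        if c <= 0.0:
            return -np.inf
        loglik += np.log(c)
        a0, a1 = a0 / c, a1 / c
    return float(loglik)


# ---------------------------------------------------------------------------
# vectorized likelihood + gradient over all sites (constant p per site)
# ---------------------------------------------------------------------------

def _forward_backward(d, m, psi1, gamma, epsilon, p):
    """Scaled forward-backward for all sites at once.

    ``d``/``m`` are (n, T) detection counts and non-missing occasion
    counts; ``psi1``/``p`` are (n,); ``gamma``/``epsilon`` are (n, T-1).
    Returns (loglik_per_site, q, xi) with state marginals
    q (n, T, 2) and pairwise marginals xi (n, T-1, 2, 2).
    """
    n, T = d.shape
    with np.errstate(divide="ignore"):
        logE1 = d * np.log(p)[:, None] + (m - d) * np.log1p(-p)[:, None]
    any_det = d > 0
    shift = np.where(any_det, logE1, np.maximum(logE1, 0.0))
    E1 = np.exp(logE1 - shift)
    E0 = np.where(any_det, 0.0, np.exp(-shift))

    ahat = np.empty((n, T, 2))
    c = np.empty((n, T))
    a0 = (1.0 - psi1) * E0[:, 0]
    a1 = psi1 * E1[:, 0]
    c[:, 0] = a0 + a1
    ahat[:, 0, 0] = a0 / c[:, 0]
    ahat[:, 0, 1] = a1 / c[:, 0]
    for t in range(T - 1):
        g = gamma[:, t]
        e = epsilon[:, t]
        pr0 = ahat[:, t, 0] * (1 - g) + ahat[:, t, 1] * e
        pr1 = ahat[:, t, 0] * g + ahat[:, t, 1] * (1 - e)
        a0 = pr0 * E0[:, t + 1]
        a1 = pr1 * E1[:, t + 1]
        c[:, t + 1] = a0 + a1
        ahat[:, t + 1, 0] = a0 / c[:, t + 1]
        ahat[:, t + 1, 1] = a1 / c[:, t + 1]

    b = np.empty((n, T, 2))
    b[:, T - 1] = 1.0
    xi = np.empty((n, max(T - 1, 0), 2, 2))
    for t in range(T - 2, -1, -1):
        g = gamma[:, t]
        e = epsilon[:, t]
        f0 = E0[:, t + 1] * b[:, t + 1, 0] / c[:, t + 1]
        f1 = E1[:, t + 1] * b[:, t + 1, 1] / c[:, t + 1]
        b[:, t, 0] = (1 - g) * f0 + g * f1
        b[:, t, 1] = e * f0 + (1 - e) * f1
        xi[:, t, 0, 0] = ahat[:, t, 0] * (1 - g) * f0
        xi[:, t, 0, 1] = ahat[:, t, 0] * g * f1
        xi[:, t, 1, 0] = ahat[:, t, 1] * e * f0
        xi[:, t, 1, 1] = ahat[:, t, 1] * (1 - e) * f1

    q = ahat * b
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=1)
    return loglik, q, xi


@dataclass
class ModelData:
    """Sufficient statistics + designs the posterior needs."""

    d: np.ndarray        # (n, T) detections per site-period
    m: np.ndarray        # (n, T) non-missing occasions per site-period
    blocks: DesignBlocks

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(self.blocks.n_sites)


def model_data_from_history(history, blocks: DesignBlocks) -> ModelData:
    """Align a DetectionHistory with design blocks (site order must match)."""
    if history.site_ids != blocks.site_ids:
        raise ValueError("history and design blocks disagree on site order")
    return ModelData(d=np.nan_to_num(history.detections()),
                     m=history.effort().astype(float), blocks=blocks)


def log_posterior_and_grad(theta: np.ndarray, data: ModelData,
                           beta_scale: float = 2.5,
                           sigma_eta_scale: float = 1.0
                           ) -> tuple[float, np.ndarray]:
    """Joint log posterior and its exact gradient.

    The likelihood gradient comes from the forward-backward marginals:
    on the logit scale the score of a transition probability is the
    expected flow through that branch minus its probability-weighted
    complement, and the detection score is the occupied-state marginal
    times the Bernoulli residual (d - m p).
    """
    blocks = data.blocks
    n, T = data.d.shape
    layout = data.layout
    s = layout.slices

    b_psi1 = theta[s["beta_psi1"]]
    b_p = theta[s["beta_p"]]
    b_g = theta[s["beta_gamma"]]
    b_e = theta[s["beta_epsilon"]]
    log_sigma = theta[s["log_sigma_eta"]][0]
    if log_sigma > 50.0:  # absurd scale: zero posterior mass, avoid overflow
        return -np.inf, np.zeros(layout.dim)
    eta_raw = theta[s["eta_raw"]]
    sigma = np.exp(log_sigma)

    psi1 = expit(blocks.X_psi1 @ b_psi1)
    p = np.clip(expit(blocks.X_p @ b_p + sigma * eta_raw), _PCLIP, 1 - _PCLIP)
    if T > 1:
        lin_g = (blocks.X_trans @ b_g).reshape(n, T - 1)
        lin_e = (blocks.X_trans @ b_e).reshape(n, T - 1)
        gamma = expit(lin_g)
        epsilon = expit(lin_e)
    else:
        gamma = epsilon = np.zeros((n, 0))
    psi1 = np.clip(psi1, _PCLIP, 1 - _PCLIP)
    gamma = np.clip(gamma, _PCLIP, 1 - _PCLIP)
    epsilon = np.clip(epsilon, _PCLIP, 1 - _PCLIP)

    loglik, q, xi = _forward_backward(data.d, data.m, psi1, gamma, epsilon, p)

    # scores on the logit scale
    g_lpsi1 = q[:, 0, 1] - psi1
    g_lp = (q[:, :, 1] * (data.d - data.m * p[:, None])).sum(axis=1)
    if T > 1:
        g_lgamma = xi[:, :, 0, 1] * (1 - gamma) - xi[:, :, 0, 0] * gamma
        g_leps = xi[:, :, 1, 0] * (1 - epsilon) - xi[:, :, 1, 1] * epsilon

    grad = np.zeros(layout.dim)
    grad[s["beta_psi1"]] = blocks.X_psi1.T @ g_lpsi1
    grad[s["beta_p"]] = blocks.X_p.T @ g_lp
    if T > 1:
        grad[s["beta_gamma"]] = blocks.X_trans.T @ g_lgamma.ravel()
        grad[s["beta_epsilon"]] = blocks.X_trans.T @ g_leps.ravel()
    grad[s["eta_raw"]] = sigma * g_lp
    grad[s["log_sigma_eta"]] = sigma * float(g_lp @ eta_raw)

    # priors
    logp = float(loglik.sum())
    betas = np.concatenate([b_psi1, b_p, b_g, b_e])
    logp += -0.5 * float(betas @ betas) / beta_scale**2
    for name in ("beta_psi1", "beta_p", "beta_gamma", "beta_epsilon"):
        grad[s[name]] += -theta[s[name]] / beta_scale**2
    logp += -0.5 * float(eta_raw @ eta_raw)
    grad[s["eta_raw"]] += -eta_raw
    # half-normal(0, scale) on sigma with log-scale Jacobian
    logp += -0.5 * (sigma / sigma_eta_scale) ** 2 + log_sigma
    grad[s["log_sigma_eta"]] += -(sigma / sigma_eta_scale) ** 2 + 1.0

    return logp, grad


def log_posterior(theta: np.ndarray, data: ModelData, **kw) -> float:
    return log_posterior_and_grad(theta, data, **kw)[0]
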