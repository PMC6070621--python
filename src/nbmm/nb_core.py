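"""Negative binomial probability computations and PQL working data.

The count model for one taxon is

    y_ij ~ NB(mu_ij, theta),   Var(y) = mu + mu^2 / theta,

with log link ``log(mu_ij) = log(T_ij) + X_ij beta + Z_ij b_i``; theta is a
single per-taxon dispersion (larger theta -> closer to Poisson).  Fitting
alternates a Newton-Raphson update of theta on the NB likelihood (at the
current conditional means) with a weighted linear-mixed-model fit of the
working response — the standard penalized quasi-likelihood linearization
for the log link:

    z_ij = eta_ij + (y_ij - mu_ij) / mu_ij
    w_ij = mu_ij * theta / (mu_ij + theta)

``w`` is the inverse of V(mu) * g'(mu)^2 with V(mu) = mu + mu^2/theta and
g'(mu) = 1/mu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma, xlogy

__all__ = [
    "NBParams",
    "PseudoData",
    "DispersionEstimate",
    "nb_logpmf",
    "estimate_dispersion",
    "pseudo_data",
    "nb_glm_irls",
]

THETA_MIN = 1e-4
THETA_MAX = 1e8
MU_FLOOR = 1e-10
#: above this eta, exp(eta) would overflow float64
ETA_MAX = 690.0


@dataclass
class NBParams:
    """Mean and dispersion of one negative binomial observation set."""

    mu: np.ndarray
    theta: float

    def __post_init__(self):
        if np.any(np.asarray(self.mu) <= 0):
            raise ValueError("mu must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def variance(self) -> np.ndarray:
        return self.mu + self.mu**2 / self.theta


@dataclass
class PseudoData:
    """Working response, weights and linear predictor for one IWLS step."""

    z: np.ndarray
    w: np.ndarray
    eta: np.ndarray
    mu: np.ndarray


@dataclass
class DispersionEstimate:
    """Result of the Newton-Raphson dispersion update."""

    theta: float
    converged: bool
    at_bound: bool
    n_iter: int
    loglik: float

    def __float__(self) -> float:
        return float(self.theta)


def _nb_ll_terms(y, mu, theta):
    """Elementwise NB log-pmf, stable for very large theta.

    For theta >> y the direct gammaln difference loses ~half the digits
    (difference of two O(theta log theta) numbers), so the two-term
    asymptotic expansion of lgamma(y+theta) - lgamma(theta) is used there.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    big = theta > 1e6 * np.maximum(np.max(y, initial=1.0), 1.0)
    if big:
        lg = y * np.log(theta) + y * (y - 1.0) / (2.0 * theta)
    else:
        lg = gammaln(y + theta) - gammaln(theta)
    return (
        lg
        - gammaln(y + 1.0)
        - theta * np.log1p(mu / theta)
        - xlogy(y, 1.0 + theta / mu)
    )


def nb_logpmf(y, mu, theta):
    """Log probability mass of NB(mu, theta) at count ``y``.

    Computed in log space throughout (lgamma, log1p); never via the Gamma
    function directly.  ``y`` must be integral and nonnegative; ``mu`` and
    ``theta`` strictly positive.  Broadcasts like numpy ufuncs.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or np.any(y_arr % 1 != 0):
        raise ValueError("y must be a nonnegative integer count")
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr <= 0):
        raise ValueError("mu must be positive")
    theta = float(theta)
    if theta <= 0:
        raise ValueError("theta must be positive")
    out = _nb_ll_terms(y_arr, mu_arr, theta)
    if np.isscalar(y) and np.isscalar(mu):
        return float(out)
    return out


def _theta_score_hess(y, mu, theta):
    """Score and Hessian of the NB log likelihood in theta (mu fixed)."""
    g = np.sum(
        digamma(y + theta)
        - digamma(theta)
        + np.log(theta)
        + 1.0
        - np.log(mu + theta)
        - (y + theta) / (mu + theta)
    )
    h = np.sum(
        polygamma(1, y + theta)
        - polygamma(1, theta)
        + 1.0 / theta
        - 1.0 / (mu + theta)
        - (mu - y) / (mu + theta) ** 2
    )
    return g, h


def estimate_dispersion(
    y,
    mu,
    theta_init: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    theta_min: float = THETA_MIN,
    theta_max: float = THETA_MAX,
) -> DispersionEstimate:
    """Maximize the NB likelihood over theta with the means held fixed.

    Newton-Raphson on ``u = log(theta)`` (which keeps theta positive) with
    analytic digamma/trigamma derivatives; when the Hessian is not negative
    a unit gradient-sign step is taken instead, and every step is halved
    until the likelihood does not decrease.  Convergence is
    ``|delta log theta| < tol``.  theta is confined to
    [``theta_min``, ``theta_max``]; under-dispersed data push theta to the
    upper cap (the Poisson limit) and the result is flagged ``at_bound``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape or y.size < 2:
        raise ValueError("y and mu must be equal-length vectors of size >= 2")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if theta_init <= 0:
        raise ValueError("theta_init must be positive")

    lo, hi = np.log(theta_min), np.log(theta_max)
    u = float(np.clip(np.log(theta_init), lo, hi))

    def ll(u_):
        return float(np.sum(_nb_ll_terms(y, mu, np.exp(u_))))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta = np.exp(u)
        g_t, h_t = _theta_score_hess(y, mu, theta)
        g_u = theta * g_t
        if abs(g_u) < 1e-10:
            converged = True
            break
        h_u = theta**2 * h_t + g_u
        if h_u < -1e-12:
            step = -g_u / h_u
        else:
            step = np.sign(g_u)
        step = float(np.clip(step, -5.0, 5.0))

        f0 = ll(u)
        u_new = float(np.clip(u + step, lo, hi))
        halvings = 0
        while ll(u_new) < f0 - 1e-12 and halvings < 30:
            step *= 0.5
            u_new = float(np.clip(u + step, lo, hi))
            halvings += 1
        delta = u_new - u
        u = u_new
        if abs(delta) < tol:
            converged = True
            break

    theta = float(np.exp(u))
    at_bound = False
    # at the caps the score may underflow to ~0, so a pinned iterate whose
    # gradient does not clearly point back inside counts as at_bound
    if u >= hi - 1e-9:
        g_t, _ = _theta_score_hess(y, mu, theta)
        at_bound = g_t >= -1e-6
        converged = converged or at_bound
    elif u <= lo + 1e-9:
        g_t, _ = _theta_score_hess(y, mu, theta)
        at_bound = g_t <= 1e-6
        converged = converged or at_bound
    return DispersionEstimate(theta, converged, at_bound, it, ll(u))


def pseudo_data(y, eta, theta: float) -> PseudoData:
    """PQL working response and weights for the NB log-link model.

    z = eta + (y - mu)/mu and w = mu*theta/(mu + theta) with mu = exp(eta).
    In the Poisson limit (theta -> inf) the weight tends to mu; when
    exp(eta) would overflow an error instructs rescaling the covariates.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if np.max(eta) > ETA_MAX:
        raise ValueError(
            "exp(eta) overflows float64; rescale covariates or the offset"
        )
    mu = np.exp(eta)
    if np.any(mu < MU_FLOOR):
        warnings.warn("fitted means floored at 1e-10", stacklevel=2)
        mu = np.maximum(mu, MU_FLOOR)
    z = eta + (y - mu) / mu
    w = mu * theta / (mu + theta)
    return PseudoData(z=z, w=w, eta=eta, mu=mu)


def nb_glm_irls(
    y,
    X,
    offset,
    theta: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fixed-effects-only NB regression by iteratively reweighted least
    squares at a fixed dispersion.

    Used to initialize the mixed-model IWLS loop (and as a standalone NB
    GLM fitter).  Returns ``(beta, eta, n_iter, converged)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    eta = np.log(y + 0.5)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pd_ = pseudo_data(y, eta, theta)
        sw = np.sqrt(pd_.w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], (pd_.z - offset) * sw, rcond=None)
        eta_new = offset + X @ beta
        delta = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        if delta < tol:
            converged = True
            break
    return beta, eta, it, converged
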