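"""Independent oracle: Poisson random-intercept GLMM by adaptive
Gauss-Hermite quadrature.

Maximizes the exact marginal likelihood

    L = prod_i  integral  prod_j Pois(y_ij | exp(offset + X beta + b)) phi(b; 0, tau^2) db

with the integral evaluated by Gauss-Hermite quadrature recentered at each
subject's posterior mode and rescaled by the posterior curvature (adaptive
quadrature).  Deliberately independent of the package's PQL machinery.
"""

import numpy as np
from scipy import optimize
from scipy.special import gammaln


def _subject_loglik(y, eta_fix, tau, nodes, weights):
    """Adaptive GH marginal log likelihood for one subject."""

    def neg_post(b):
        lam = np.exp(eta_fix + b)
        return -(np.sum(y * (eta_fix + b) - lam) - 0.5 * b**2 / tau**2)

    res = optimize.minimize_scalar(neg_post, bounds=(-10, 10), method="bounded")
    b_hat = res.x
    curv = np.sum(np.exp(eta_fix + b_hat)) + 1.0 / tau**2  # -d2 log posterior
    scale = 1.0 / np.sqrt(curv)

    b = b_hat + np.sqrt(2.0) * scale * nodes
    log_integrand = (
        np.sum(
            y[:, None] * (eta_fix[:, None] + b[None, :])
            - np.exp(eta_fix[:, None] + b[None, :])
            - gammaln(y + 1.0)[:, None],
            axis=0,
        )
        - 0.5 * b**2 / tau**2
        - 0.5 * np.log(2.0 * np.pi * tau**2)
    )
    # int f(b) db  ~=  sqrt(2)*scale * sum w_k e^{x_k^2} f(b_k)
    vals = log_integrand + nodes**2 + np.log(weights) + 0.5 * np.log(2.0) + np.log(scale)
    m = vals.max()
    return m + np.log(np.sum(np.exp(vals - m)))


def fit_poisson_glmm_aghq(y, X, offset, groups, n_nodes=31):
    """ML fit of the Poisson random-intercept model; returns (beta, tau)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    rows = [np.flatnonzero(groups == g) for g in labels]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def nll(params):
        beta = params[:-1]
        tau = np.exp(params[-1])
        eta = offset + X @ beta
        total = 0.0
        for r in rows:
            total += _subject_loglik(y[r], eta[r], tau, nodes, weights)
        return -total

    p = X.shape[1]
    x0 = np.zeros(p + 1)
    x0[0] = np.log(y.mean() + 0.5) - np.mean(offset)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    return res.x[:-1], float(np.exp(res.x[-1]))
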