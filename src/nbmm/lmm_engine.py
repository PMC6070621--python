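"""Weighted linear mixed model with structured within-subject correlation.

The working model fitted once per IWLS iteration is, per subject i,

    z_i = X_i beta + Z_i b_i + W_i^{-1/2} e_i,
    b_i ~ N(0, Psi),   e_i ~ N(0, sigma^2 R_i),

so the marginal covariance of z_i is

    V_i = Z_i Psi Z_i' + sigma^2 W_i^{-1/2} R_i W_i^{-1/2}.

R_i is the identity (independent errors), order-based AR(1)
(rho^|j-k|) or continuous-time AR(1) (rho^|t_j - t_k|).  Psi may be a
general positive-definite matrix (log-Cholesky parameterization) or
diagonal (log standard deviations).

Estimation is maximum likelihood with beta and sigma^2 profiled out:
writing Psi = sigma^2 G, only the relative covariance G and the
correlation parameter are optimized (quasi-Newton, numerically
differenced); at each candidate the GLS beta and the closed-form sigma^2
are plugged in.  All per-subject operations are batched over subjects of
equal size, which keeps a full fit at a few milliseconds for typical
longitudinal layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "RandomEffectsCov",
    "ResidualCorrelation",
    "LMMFit",
    "build_correlation",
    "lmm_loglik",
    "fit_lmm",
    "predict_re_loo",
    "wald_inference",
]

_PENALTY = 1e10
_PHI_BOUND = 12.0


@dataclass
class RandomEffectsCov:
    """Random-effects covariance Psi and its unconstrained parameterization.

    ``structure="general_pd"`` uses log-Cholesky (diagonal of the Cholesky
    factor on the log scale, off-diagonals free); ``"diagonal"`` uses log
    standard deviations.
    """

    structure: str
    dim: int

    def __post_init__(self):
        if self.structure not in ("general_pd", "diagonal"):
            raise ValueError(f"unknown random-effects structure {self.structure!r}")
        if self.dim < 0:
            raise ValueError("dimension must be nonnegative")

    @property
    def n_params(self) -> int:
        if self.dim == 0:
            return 0
        if self.structure == "diagonal":
            return self.dim
        return self.dim * (self.dim + 1) // 2

    def matrix(self, params: np.ndarray) -> np.ndarray:
        """Relative covariance G (Psi / sigma^2) implied by ``params``."""
        q = self.dim
        if q == 0:
            return np.zeros((0, 0))
        params = np.asarray(params, dtype=float)
        if self.structure == "diagonal":
            return np.diag(np.exp(2.0 * params))
        L = np.zeros((q, q))
        rows, cols = np.tril_indices(q)
        L[rows, cols] = params
        L[np.diag_indices(q)] = np.exp(np.diagonal(L))
        return L @ L.T


@dataclass
class ResidualCorrelation:
    """Within-subject residual correlation: kind, rho and scale sigma^2."""

    kind: str = "independent"
    rho: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self):
        if self.kind not in ("independent", "ar1", "car1"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def matrix(self, times: np.ndarray) -> np.ndarray:
        return build_correlation(self.kind, self.rho, times=times)


def build_correlation(kind: str, rho: float, times=None, n: int | None = None):
    """Correlation matrix R for one subject.

    ``ar1`` is indexed by observation order (entry (j,k) = rho^|j-k|, any
    |rho| < 1); ``car1`` by continuous time gaps (rho^|t_j - t_k|, which is
    positive definite only for rho in (0, 1)); ``independent`` is the
    identity.
    """
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be a 1-d vector")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing within a subject")
        n = times.size
    if n is None:
        raise ValueError("provide times or n")
    if kind == "independent":
        return np.eye(n)
    if kind == "ar1":
        if abs(rho) >= 1:
            raise ValueError("AR(1) requires |rho| < 1")
        lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        return float(rho) ** lag if rho != 0 else np.eye(n)
    if kind == "car1":
        if not 0 < rho < 1:
            raise ValueError("continuous AR(1) requires rho in (0, 1)")
        if times is None:
            raise ValueError("car1 requires measurement times")
        dt = np.abs(np.subtract.outer(times, times))
        return float(rho) ** dt
    raise ValueError(f"unknown correlation kind {kind!r}")


# ---------------------------------------------------------------------------
# grouped data, batched by subject size
# ---------------------------------------------------------------------------


@dataclass
class _Batch:
    X: np.ndarray  # (B, s, p)
    Z: np.ndarray  # (B, s, q)
    z: np.ndarray  # (B, s)
    isw: np.ndarray  # (B, s) 1/sqrt(w)
    lag: np.ndarray  # (s, s) |j - k|
    dt: np.ndarray  # (B, s, s) |t_j - t_k|
    subj_idx: np.ndarray  # (B,) positions into the subject list


@dataclass
class _GroupedData:
    batches: list
    codes: np.ndarray
    subjects: np.ndarray
    row_lists: list
    N: int
    p: int
    q: int


def _group_data(z, w, X, Z, groups, times) -> _GroupedData:
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    if Z is None:
        Z = np.zeros((N, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    q = Z.shape[1]
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    codes, subjects = pd.factorize(np.asarray(groups))
    if times is None:
        times = np.arange(N, dtype=float)
    times = np.asarray(times, dtype=float)

    row_lists = [np.flatnonzero(codes == c) for c in range(len(subjects))]
    by_size: dict[int, list[int]] = {}
    for i, rows in enumerate(row_lists):
        by_size.setdefault(len(rows), []).append(i)

    batches = []
    for s, subj_ids in sorted(by_size.items()):
        idx = np.stack([row_lists[i] for i in subj_ids])  # (B, s)
        tb = times[idx]
        batches.append(
            _Batch(
                X=X[idx],
                Z=Z[idx],
                z=z[idx],
                isw=1.0 / np.sqrt(w[idx]),
                lag=np.abs(np.subtract.outer(np.arange(s), np.arange(s))),
                dt=np.abs(tb[:, :, None] - tb[:, None, :]),
                subj_idx=np.asarray(subj_ids),
            )
        )
    return _GroupedData(batches, codes, subjects, row_lists, N, p, q)


def _batch_R(batch: _Batch, kind: str, rho: float) -> np.ndarray:
    if kind == "independent" or rho == 0.0:
        return np.eye(batch.lag.shape[0])
    if kind == "ar1":
        return float(rho) ** batch.lag
    return float(rho) ** batch.dt  # car1: (B, s, s)


def _batch_cov(batch: _Batch, G: np.ndarray, kind: str, rho: float) -> np.ndarray:
    """Per-subject relative covariance C_i = Z_i G Z_i' + W^{-1/2} R W^{-1/2}."""
    R = _batch_R(batch, kind, rho)
    C = batch.isw[:, :, None] * R * batch.isw[:, None, :]
    if G.shape[0]:
        C = C + np.einsum("bsq,qr,btr->bst", batch.Z, G, batch.Z)
    return C


def _profiled_nll(phi, gd: _GroupedData, recov: RandomEffectsCov, kind: str,
                  reml: bool = False):
    """Negative profiled (restricted) log likelihood; also returns
    (beta, sigma2, XtCX)."""
    n_g = recov.n_params
    G = recov.matrix(phi[:n_g])
    rho = _rho_from_param(kind, phi[n_g]) if kind != "independent" else 0.0

    p = gd.p
    XtCX = np.zeros((p, p))
    XtCz = np.zeros(p)
    ztCz = 0.0
    logdet = 0.0
    for b in gd.batches:
        C = _batch_cov(b, G, kind, rho)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return _PENALTY * (1.0 + float(np.sum(np.square(phi)))), None
        logdet += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        rhs = np.concatenate([b.X, b.z[:, :, None]], axis=2)
        sol = np.linalg.solve(L, rhs)
        Xt, zt = sol[:, :, :p], sol[:, :, p]
        XtCX += np.einsum("bsi,bsj->ij", Xt, Xt)
        XtCz += np.einsum("bsi,bs->i", Xt, zt)
        ztCz += float(np.sum(zt * zt))
    try:
        beta = np.linalg.solve(XtCX, XtCz)
    except np.linalg.LinAlgError:
        return _PENALTY * (1.0 + float(np.sum(np.square(phi)))), None
    rss = max(ztCz - float(beta @ XtCz), 1e-300)
    if reml:
        dof = gd.N - p
        sigma2 = rss / dof
        sign, logdet_x = np.linalg.slogdet(XtCX)
        if sign <= 0:
            return _PENALTY * (1.0 + float(np.sum(np.square(phi)))), None
        nll = 0.5 * (
            dof * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0) + logdet + logdet_x
        )
    else:
        sigma2 = rss / gd.N
        nll = 0.5 * (gd.N * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0) + logdet)
    if not np.isfinite(nll):
        return _PENALTY * (1.0 + float(np.sum(np.square(phi)))), None
    return nll, (beta, sigma2, XtCX)


def _rho_from_param(kind: str, x: float) -> float:
    if kind == "ar1":
        return float(np.tanh(x))
    return float(special.expit(x))  # car1 in (0, 1)


def _rho_to_param(kind: str, rho: float) -> float:
    if kind == "ar1":
        return float(np.arctanh(np.clip(rho, -0.999999, 0.999999)))
    return float(special.logit(np.clip(rho, 1e-6, 1 - 1e-6)))


# ---------------------------------------------------------------------------
# public likelihood and fitting
# ---------------------------------------------------------------------------


def lmm_loglik(
    beta,
    sigma2: float,
    psi,
    z,
    w,
    X,
    Z,
    groups,
    times=None,
    correlation: str = "independent",
    rho: float = 0.0,
) -> float:
    """Exact multivariate-normal log likelihood of the working model.

    Evaluates, blockwise per subject via Cholesky factorizations,
    sum_i log N(z_i | X_i beta, Z_i Psi Z_i' + sigma^2 W_i^{-1/2} R_i W_i^{-1/2}).
    """
    beta = np.asarray(beta, dtype=float)
    psi = np.atleast_2d(np.asarray(psi, dtype=float)) if np.size(psi) else np.zeros((0, 0))
    gd = _group_data(z, w, X, Z, groups, times)
    if psi.shape != (gd.q, gd.q):
        raise ValueError(f"psi must be {gd.q}x{gd.q}")
    G = psi / sigma2
    ll = 0.0
    for b in gd.batches:
        C = sigma2 * _batch_cov(b, G, correlation, rho)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as err:
            bad = gd.subjects[b.subj_idx[0]]
            raise ValueError(f"non-positive-definite covariance (subject {bad!r})") from err
        r = b.z - np.einsum("bsp,p->bs", b.X, beta)
        u = np.linalg.solve(L, r[:, :, None])[:, :, 0]
        s = b.lag.shape[0]
        ll -= 0.5 * (
            float(np.sum(u * u))
            + 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            + b.X.shape[0] * s * np.log(2.0 * np.pi)
        )
    return ll


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the weighted correlated LMM."""

    beta: np.ndarray
    beta_names: list
    cov_beta: np.ndarray
    sigma2: float
    psi: np.ndarray
    re_structure: str
    correlation: str
    rho: float | None
    loglik: float
    converged: bool
    blups: np.ndarray  # (n_subjects, q)
    subjects: np.ndarray
    n_obs: int
    n_groups: int
    varies_within: np.ndarray  # per fixed column
    is_intercept: np.ndarray
    opt_params: np.ndarray
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _column_roles(X, codes):
    """Flag intercept columns and columns varying within some subject."""
    N, p = X.shape
    is_intercept = np.array([np.all(X[:, j] == 1.0) for j in range(p)])
    varies = np.zeros(p, dtype=bool)
    n_groups = codes.max() + 1
    for j in range(p):
        mx = np.full(n_groups, -np.inf)
        mn = np.full(n_groups, np.inf)
        np.maximum.at(mx, codes, X[:, j])
        np.minimum.at(mn, codes, X[:, j])
        varies[j] = np.any(mx - mn > 1e-12)
    return is_intercept, varies


def fit_lmm(
    z,
    w,
    X,
    Z,
    groups,
    times=None,
    *,
    re_structure: str = "general_pd",
    correlation: str = "independent",
    beta_names=None,
    start: np.ndarray | None = None,
    gtol: float = 1e-8,
    max_restarts: int = 2,
    reml: bool = False,
) -> LMMFit:
    """Fit the weighted LMM by maximum likelihood (or REML).

    ``Z=None`` drops the random effects entirely (the fit reduces to
    weighted GLS).  ``start`` warm-starts the variance-parameter search,
    which the IWLS driver exploits across iterations.  On a failed search
    up to ``max_restarts`` perturbed restarts are attempted and the best
    point is kept; the fit is then flagged unconverged but still usable.
    Rows must be ordered by time within subject for order-based AR(1).
    """
    gd = _group_data(z, w, X, Z, groups, times)
    X_arr = np.asarray(X, dtype=float)
    if X_arr.ndim == 1:
        X_arr = X_arr[:, None]
    if np.linalg.matrix_rank(X_arr) < gd.p:
        names = beta_names or [f"x{j}" for j in range(gd.p)]
        _, Rq = np.linalg.qr(X_arr)
        bad = [names[j] for j in range(gd.p) if abs(Rq[j, j]) < 1e-8 * abs(Rq[0, 0])]
        raise ValueError(f"fixed-effects design is singular; collinear columns: {bad}")
    recov = RandomEffectsCov(re_structure, gd.q)
    n_phi = recov.n_params + (0 if correlation == "independent" else 1)

    def objective(phi):
        return _profiled_nll(phi, gd, recov, correlation, reml)[0]

    phi0 = np.zeros(n_phi)
    if correlation == "car1":
        phi0[-1] = 0.0  # expit(0) = 0.5
    if start is not None and len(start) == n_phi:
        phi0 = np.asarray(start, dtype=float)

    converged = True
    message = ""
    if n_phi == 0:
        phi_hat = phi0
    else:
        bounds = [(-_PHI_BOUND, _PHI_BOUND)] * n_phi
        res = optimize.minimize(
            objective,
            phi0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": gtol, "maxiter": 500},
        )
        best = res
        if (not res.success and "ABNORMAL" in str(res.message).upper()) or res.fun >= _PENALTY:
            rng = np.random.default_rng(20180726)
            for _ in range(max_restarts):
                trial = optimize.minimize(
                    objective,
                    phi0 + rng.normal(scale=1.0, size=n_phi),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": 1e-12, "gtol": gtol, "maxiter": 500},
                )
                if trial.fun < best.fun:
                    best = trial
        phi_hat = best.x
        converged = bool(best.fun < _PENALTY)
        message = str(best.message)

    nll, extras = _profiled_nll(phi_hat, gd, recov, correlation, reml)
    if extras is None:
        raise ValueError("likelihood evaluation failed at the optimum")
    beta, sigma2, XtCX = extras
    G = recov.matrix(phi_hat[: recov.n_params])
    rho = (
        _rho_from_param(correlation, phi_hat[-1])
        if correlation != "independent"
        else None
    )

    # BLUPs b_i = G Z_i' C_i^{-1} (z_i - X_i beta)
    blups = np.zeros((len(gd.subjects), gd.q))
    for b in gd.batches:
        C = _batch_cov(b, G, correlation, rho if rho is not None else 0.0)
        r = b.z - np.einsum("bsp,p->bs", b.X, beta)
        Cinv_r = np.linalg.solve(C, r[:, :, None])[:, :, 0]
        if gd.q:
            blups[b.subj_idx] = np.einsum("qr,bsr,bs->bq", G, b.Z, Cinv_r)

    is_intercept, varies = _column_roles(X_arr, gd.codes)
    if beta_names is None:
        beta_names = [f"x{j}" for j in range(gd.p)]
    # finite-sample factor N/(N-p) on the fixed-effect covariance under ML,
    # matching the reference longitudinal LMM software (REML needs none:
    # sigma2 is already divided by N-p there)
    adj = 1.0 if reml else gd.N / max(gd.N - gd.p, 1)
    return LMMFit(
        beta=beta,
        beta_names=list(beta_names),
        cov_beta=adj * sigma2 * np.linalg.inv(XtCX),
        sigma2=sigma2,
        psi=sigma2 * G,
        re_structure=re_structure,
        correlation=correlation,
        rho=rho,
        loglik=-nll,
        converged=converged,
        blups=blups,
        subjects=gd.subjects,
        n_obs=gd.N,
        n_groups=len(gd.subjects),
        varies_within=varies,
        is_intercept=is_intercept,
        opt_params=np.asarray(phi_hat, dtype=float),
        message=message,
    )


def predict_re_loo(fit: LMMFit, z, w, X, Z, groups, times=None) -> np.ndarray:
    """Per-observation leave-one-out random-effect predictions.

    Row (i, j) holds the BLUP of subject i's random effects computed from
    that subject's other observations only.  With A_i = C_i^{-1} and
    g_i = A_i (z_i - X_i beta), the partitioned-inverse downdate gives

        b_i^{(-j)} = b_i - G Z_i' A_i[:, j] * g_ij / A_i[j, j],

    so no refitting is needed.  Used to evaluate the NB likelihood for the
    dispersion update at predictive rather than self-fitted means, which
    removes the shrinkage-overfitting bias of the plug-in estimate.
    """
    gd = _group_data(z, w, X, Z, groups, times)
    G = fit.psi / fit.sigma2
    rho = fit.rho if fit.rho is not None else 0.0
    out = np.zeros((gd.N, gd.q))
    for b in gd.batches:
        C = _batch_cov(b, G, fit.correlation, rho)
        A = np.linalg.inv(C)
        r = b.z - np.einsum("bsp,p->bs", b.X, fit.beta)
        g = np.einsum("bst,bt->bs", A, r)
        if gd.q == 0:
            continue
        full = np.einsum("qr,bsr,bs->bq", G, b.Z, g)  # ordinary BLUP
        GZtA = np.einsum("qr,bsr,bsj->bqj", G, b.Z, A)
        diagA = np.diagonal(A, axis1=1, axis2=2)
        corr = GZtA * (g / diagA)[:, None, :]  # (B, q, s)
        loo = full[:, :, None] - corr  # (B, q, s) per left-out obs
        rows = np.stack([gd.row_lists[i] for i in b.subj_idx])  # (B, s)
        out[rows.reshape(-1)] = np.moveaxis(loo, 1, 2).reshape(-1, gd.q)
    return out


def wald_inference(fit: LMMFit) -> pd.DataFrame:
    """Per-coefficient Wald t-tests with containment degrees of freedom.

    Terms that vary within subjects (time, interactions, and the
    intercept) are tested against N - n_subjects - p_within df; terms
    constant within subjects (e.g. the group indicator) against
    n_subjects - 1 - p_between df — the inner-outer rule used by standard
    longitudinal LMM software.
    """
    inner = fit.varies_within & ~fit.is_intercept
    outer = ~fit.varies_within & ~fit.is_intercept
    df_inner = max(fit.n_obs - fit.n_groups - int(inner.sum()), 1)
    df_outer = max(fit.n_groups - 1 - int(outer.sum()), 1)
    df = np.where(fit.varies_within | fit.is_intercept, df_inner, df_outer).astype(float)
    se = fit.se
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.beta / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"estimate": fit.beta, "se": se, "t": t, "df": df, "p": p},
        index=fit.beta_names,
    )
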