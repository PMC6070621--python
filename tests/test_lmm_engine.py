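import numpy as np
import pytest
from scipy import stats

from nbmm import build_correlation, fit_lmm, lmm_loglik, wald_inference


def simulate_lmm(rng, n_subj=30, n_per=4, tau=0.6, sigma=1.0, rho=0.0,
                 kind="independent", beta=(1.0, 0.5, -0.3, 0.2), weights=None):
    t = np.tile(np.linspace(0, 1, n_per), n_subj)
    subj = np.repeat(np.arange(n_subj), n_per)
    x = np.repeat((np.arange(n_subj) < n_subj // 2).astype(float), n_per)
    X = np.column_stack([np.ones(n_subj * n_per), x, t, x * t])
    Z = np.ones((n_subj * n_per, 1))
    w = weights if weights is not None else np.ones(n_subj * n_per)
    b = rng.normal(0, tau, size=n_subj)[subj]
    if kind == "ar1" and rho != 0:
        e = np.empty(n_subj * n_per)
        for i in range(n_subj):
            sl = slice(i * n_per, (i + 1) * n_per)
            ei = np.empty(n_per)
            ei[0] = rng.normal(0, sigma)
            for j in range(1, n_per):
                ei[j] = rho * ei[j - 1] + rng.normal(0, sigma * np.sqrt(1 - rho**2))
            e[sl] = ei
    else:
        e = rng.normal(0, sigma, size=n_subj * n_per)
    z = X @ np.asarray(beta) + b + e / np.sqrt(w)
    return z, w, X, Z, subj, t


class TestBuildCorrelation:
    def test_ar1_rho_zero_is_identity(self):
        np.testing.assert_array_equal(
            build_correlation("ar1", 0.0, times=[1.0, 2.0, 5.0]), np.eye(3)
        )

    def test_ar1_powers_of_rho_by_lag(self):
        R = build_correlation("ar1", 0.5, n=3)
        np.testing.assert_allclose(R[0], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_car1_powers_of_rho_by_time_gap(self):
        R = build_correlation("car1", 0.5, times=[0.0, 0.5, 2.0])
        assert R[0, 1] == pytest.approx(0.5**0.5)
        assert R[0, 2] == pytest.approx(0.25)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            build_correlation("ar1", 1.0, n=3)
        with pytest.raises(ValueError):
            build_correlation("car1", -0.2, times=[0.0, 1.0])

    def test_negative_ar1_rho_allowed(self):
        R = build_correlation("ar1", -0.4, n=3)
        assert R[0, 1] == pytest.approx(-0.4)
        assert R[0, 2] == pytest.approx(0.16)
        np.linalg.cholesky(R)  # still positive definite


class TestLMMLogLik:
    def test_independence_reduces_to_univariate_normals(self, rng):
        n = 12
        z = rng.normal(size=n)
        X = np.ones((n, 1))
        groups = np.repeat(np.arange(4), 3)
        ll = lmm_loglik(
            beta=[0.0], sigma2=1.0, psi=np.zeros((1, 1)), z=z, w=np.ones(n),
            X=X, Z=np.ones((n, 1)), groups=groups,
        )
        expected = stats.norm.logpdf(z).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_multivariate_normal(self, rng):
        """Blockwise Cholesky evaluation equals the stacked dense MVN density."""
        for _ in range(20):
            n_subj = int(rng.integers(2, 5))
            n_per = int(rng.integers(2, 5))
            N = n_subj * n_per
            X = np.column_stack([np.ones(N), rng.normal(size=N)])
            Z = np.column_stack([np.ones(N), rng.uniform(0, 1, N)])
            groups = np.repeat(np.arange(n_subj), n_per)
            times = np.tile(np.sort(rng.uniform(0, 1, n_per)), n_subj)
            w = rng.uniform(0.5, 2.0, N)
            beta = rng.normal(size=2)
            A = rng.normal(size=(2, 2)) * 0.5
            psi = A @ A.T + 0.1 * np.eye(2)
            sigma2 = float(rng.uniform(0.5, 2.0))
            rho = float(rng.uniform(0.05, 0.6))
            z = rng.normal(size=N)

            ll = lmm_loglik(beta, sigma2, psi, z, w, X, Z, groups, times,
                            correlation="car1", rho=rho)

            V = np.zeros((N, N))
            for i in range(n_subj):
                sl = slice(i * n_per, (i + 1) * n_per)
                Ri = build_correlation("car1", rho, times=times[sl])
                Wi = np.diag(1.0 / np.sqrt(w[sl]))
                V[sl, sl] = Z[sl] @ psi @ Z[sl].T + sigma2 * Wi @ Ri @ Wi
            ref = stats.multivariate_normal.logpdf(z, mean=X @ beta, cov=V)
            assert ll == pytest.approx(ref, abs=1e-8)

    def test_gaussian_scale_property(self):
        n = 10
        z = np.zeros(n)
        X = np.ones((n, 1))
        groups = np.arange(n)
        args = dict(z=z, w=np.ones(n), X=X, Z=np.ones((n, 1)), groups=groups)
        ll1 = lmm_loglik([0.0], 1.0, np.zeros((1, 1)), **args)
        ll2 = lmm_loglik([0.0], 2.0, np.zeros((1, 1)), **args)
        assert ll1 - ll2 == pytest.approx(n / 2 * np.log(2.0), abs=1e-10)


def anova_ml_oneway(z, n_subj, n_per):
    """Textbook ML estimates for the balanced one-way random-effects model."""
    zm = z.reshape(n_subj, n_per)
    grand = zm.mean()
    ssw = ((zm - zm.mean(axis=1, keepdims=True)) ** 2).sum()
    ssb = n_per * ((zm.mean(axis=1) - grand) ** 2).sum()
    sigma2_e = ssw / (n_subj * (n_per - 1))
    tau2 = max(ssb / n_subj - sigma2_e, 0.0) / n_per
    return grand, sigma2_e, tau2


class TestFitLMM:
    def test_no_random_effects_reduces_to_ols(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        z = rng.normal(size=n)
        fit = fit_lmm(z, np.ones(n), X, None, groups=np.arange(n))
        ref = np.linalg.lstsq(X, z, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ref, atol=1e-10)

    def test_balanced_anova_closed_form(self, rng):
        n_subj, n_per = 10, 4
        b = np.repeat(rng.normal(0, 0.8, n_subj), n_per)
        z = 2.0 + b + rng.normal(0, 1.0, n_subj * n_per)
        subj = np.repeat(np.arange(n_subj), n_per)
        fit = fit_lmm(z, np.ones_like(z), np.ones((len(z), 1)),
                      np.ones((len(z), 1)), subj)
        mu, sig2, tau2 = anova_ml_oneway(z, n_subj, n_per)
        assert fit.beta[0] == pytest.approx(mu, abs=1e-7)
        assert fit.sigma2 == pytest.approx(sig2, rel=1e-4)
        assert fit.psi[0, 0] == pytest.approx(tau2, rel=1e-3, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=40)
        fit = fit_lmm(z, w, X, Z, subj, t)
        ref = sm.regression.mixed_linear_model.MixedLM(z, X, groups=subj).fit(
            reml=False
        )
        np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        # nlme-convention finite-sample factor on the covariance
        adj = np.sqrt(len(z) / (len(z) - X.shape[1]))
        np.testing.assert_allclose(fit.se, np.asarray(ref.bse)[:4] * adj, rtol=1e-4)

    def test_reml_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=30)
        fit = fit_lmm(z, w, X, Z, subj, t, reml=True)
        ref = sm.regression.mixed_linear_model.MixedLM(z, X, groups=subj).fit(
            reml=True
        )
        np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-6)
        np.testing.assert_allclose(fit.se, np.asarray(ref.bse)[:4], rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_ar1_parameter_recovery(self, rng):
        tau, sigma, rho = 0.7, 0.8, 0.4
        z, w, X, Z, subj, t = simulate_lmm(
            rng, n_subj=200, n_per=6, tau=tau, sigma=sigma, rho=rho, kind="ar1"
        )
        fit = fit_lmm(z, w, X, Z, subj, t, correlation="ar1")
        assert fit.converged
        # 3-sigma-ish Monte-Carlo bands for n=200 subjects
        assert abs(fit.rho - rho) < 0.12
        assert abs(fit.sigma2 - sigma**2) < 0.15
        assert abs(fit.psi[0, 0] - tau**2) < 0.2

    def test_optimum_beats_random_parameter_draws(self, rng):
        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=15, n_per=3)
        fit = fit_lmm(z, w, X, Z, subj, t, correlation="ar1")
        for _ in range(50):
            psi = np.exp(rng.normal(scale=1.0, size=(1, 1)))
            rho = float(rng.uniform(-0.9, 0.9))
            sigma2 = float(np.exp(rng.normal()))
            ll = lmm_loglik(fit.beta, sigma2, psi, z, w, X, Z, subj, t,
                            correlation="ar1", rho=rho)
            assert fit.loglik >= ll - 1e-8

    def test_invariant_to_subject_relabeling(self, rng):
        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=12, n_per=3)
        fit1 = fit_lmm(z, w, X, Z, subj, t)
        perm = rng.permutation(len(z))
        fit2 = fit_lmm(z[perm], w[perm], X[perm], Z[perm], subj[perm], t[perm])
        np.testing.assert_allclose(np.sort(fit1.beta), np.sort(fit2.beta), atol=1e-6)
        np.testing.assert_allclose(fit1.loglik, fit2.loglik, atol=1e-6)

    def test_gls_identity_at_optimum(self, rng):
        """The returned beta equals the GLS closed form at the fitted
        variance parameters."""
        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=20, n_per=3)
        fit = fit_lmm(z, w, X, Z, subj, t)
        N = len(z)
        V = np.zeros((N, N))
        for i in np.unique(subj):
            rows = np.flatnonzero(subj == i)
            Wi = np.diag(1.0 / np.sqrt(w[rows]))
            V[np.ix_(rows, rows)] = (
                Z[rows] @ fit.psi @ Z[rows].T + fit.sigma2 * Wi @ np.eye(len(rows)) @ Wi
            )
        Vinv = np.linalg.inv(V)
        ref = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ z)
        np.testing.assert_allclose(fit.beta, ref, atol=1e-8)

    def test_singular_design_names_columns(self, rng):
        n = 12
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(rng.normal(size=n), np.ones(n), X, None,
                    groups=np.arange(n), beta_names=["I", "a", "b"])

    def test_single_observation_subjects_allowed(self, rng):
        z = rng.normal(size=5)
        fit = fit_lmm(z, np.ones(5), np.ones((5, 1)), np.ones((5, 1)),
                      groups=np.arange(5))
        assert np.isfinite(fit.loglik)


class TestWaldInference:
    def make_fit(self, rng, n_subj=20, n_per=4):
        z, w, X, Z, subj, t = simulate_lmm(rng, n_subj=n_subj, n_per=n_per,
                                           beta=(0, 0, 0, 0))
        return fit_lmm(z, w, X, Z, subj, t,
                       beta_names=["Intercept", "g", "t", "g:t"])

    def test_containment_df(self, rng):
        fit = self.make_fit(rng)
        tbl = wald_inference(fit)
        N, n = 80, 20
        assert tbl.loc["g", "df"] == n - 1 - 1  # between-subject term
        assert tbl.loc["t", "df"] == N - n - 2  # within-subject terms
        assert tbl.loc["g:t", "df"] == N - n - 2
        assert tbl.loc["Intercept", "df"] == N - n - 2

    def test_zero_estimate_gives_p_one(self, rng):
        fit = self.make_fit(rng)
        fit.beta[1] = 0.0
        tbl = wald_inference(fit)
        assert tbl.loc["g", "p"] == pytest.approx(1.0)

    def test_sign_flip_leaves_p_unchanged(self, rng):
        fit = self.make_fit(rng)
        p1 = wald_inference(fit).loc["g", "p"]
        fit.beta[1] = -fit.beta[1]
        p2 = wald_inference(fit).loc["g", "p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_t_quantile_identity(self, rng):
        # |t| = 2.086 on 20 df sits exactly at the two-sided 5% point
        fit = self.make_fit(rng)
        se = fit.se[1]
        fit.beta[1] = 2.086 * se
        fit.n_obs = 20 + fit.n_groups + 1  # force df_outer irrelevant
        p = 2 * stats.t.sf(2.086, 20)
        assert p == pytest.approx(0.05, abs=5e-4)
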