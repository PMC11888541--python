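import numpy as np
import pytest
import scipy.optimize
import statsmodels.api as sm

from crumblr import (
    cross_covariance,
    eb_moderate,
    fit_composition,
    fit_weighted_lm,
    fit_weighted_lmm,
    lmm_cross_covariance,
)
from crumblr.clr import crumblr
from crumblr.regression import _trigamma_inverse
from scipy.special import polygamma
from scipy.stats import kstest


def _random_problem(rng, n=20, c=3, weighted=True):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, c - 1))])
    y = rng.standard_normal(n)
    w = rng.uniform(0.2, 5.0, n) if weighted else np.ones(n)
    return y, X, w


class TestWeightedLM:
    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(0)
        y, X, _ = _random_problem(rng, weighted=False)
        fit = fit_weighted_lm(y, X)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.sigma2, ols.mse_resid, rtol=1e-10)

    def test_intercept_only_is_weighted_mean(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(10)
        w = rng.uniform(0.5, 2.0, 10)
        fit = fit_weighted_lm(y, np.ones((10, 1)), w)
        np.testing.assert_allclose(fit.beta[0], np.average(y, weights=w), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numerical_minimizer(self, seed):
        """WLS coefficients agree with an independent gradient-based
        minimization of the weighted sum of squares."""
        rng = np.random.default_rng(seed)
        y, X, w = _random_problem(rng)

        def fun(b):
            r = y - X @ b
            return float(w @ r**2)

        def jac(b):
            return -2.0 * X.T @ (w * (y - X @ b))

        res = scipy.optimize.minimize(fun, np.zeros(3), jac=jac, method="BFGS",
                                      options={"gtol": 1e-14})
        fit = fit_weighted_lm(y, X, w)
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(15)
        X = np.column_stack([np.ones(15), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_weighted_lm(rng.standard_normal(15), X, columns=["i", "a", "b"])

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        y, X, w = _random_problem(rng)
        f1 = fit_weighted_lm(y, X, w)
        f2 = fit_weighted_lm(y, X, 13.7 * w)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)
        np.testing.assert_allclose(f1.Sigma, f2.Sigma, atol=1e-10)


class TestCrossCovariance:
    @pytest.mark.parametrize("n,m,c,seed", [(20, 3, 2, 0), (50, 6, 4, 1), (30, 4, 3, 2)])
    def test_equal_weights_match_kronecker_form(self, n, m, c, seed):
        """With shared unit weights the pairwise formula reduces to
        cov(vec(B)) = cov(R) kron (X'X)^{-1}."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, c - 1))])
        Y = rng.standard_normal((n, m))
        fits = [fit_weighted_lm(Y[:, j], X) for j in range(m)]
        for k in range(c):
            cov = cross_covariance(fits, k)
            B = np.linalg.solve(X.T @ X, X.T @ Y)
            R = Y - X @ B
            covR = R.T @ R / (n - c)
            expected = covR * np.linalg.inv(X.T @ X)[k, k]
            np.testing.assert_allclose(cov.omega, expected, atol=1e-8)
        assert cov.nu == n - c

    def test_diagonal_is_wls_variance(self):
        rng = np.random.default_rng(4)
        n = 25
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fits = []
        for j in range(3):
            y = rng.standard_normal(n)
            w = rng.uniform(0.2, 3.0, n)
            fits.append(fit_weighted_lm(y, X, w))
        cov = cross_covariance(fits, 1)
        for j, f in enumerate(fits):
            np.testing.assert_allclose(cov.omega[j, j], f.Sigma[1, 1], rtol=1e-10)

    def test_independent_clusters_have_null_covariance(self):
        """Across replicates with independent errors, the sampling covariance
        of the two coefficient estimates is statistically zero, and so is the
        average estimated cross-covariance."""
        rng = np.random.default_rng(5)
        n, R = 200, 500
        b1, b2, omegas = [], [], []
        for _ in range(R):
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            f1 = fit_weighted_lm(rng.standard_normal(n), X)
            f2 = fit_weighted_lm(rng.standard_normal(n), X)
            b1.append(f1.beta[1])
            b2.append(f2.beta[1])
            omegas.append(cross_covariance([f1, f2], 1).omega[0, 1])
        b1, b2 = np.array(b1), np.array(b2)
        samp_cov = np.cov(b1, b2)[0, 1]
        se = np.sqrt(b1.var() * b2.var() / (R - 1))
        assert abs(samp_cov) < 3 * se
        assert abs(np.mean(omegas)) < 3 * np.std(omegas) / np.sqrt(R)


class TestEmpiricalBayes:
    def test_identical_variances_untouched_prior_diverges(self):
        # at large residual df the log-variance bias correction vanishes and
        # the posterior sits at the common value; the prior df is capped
        s2 = np.full(6, 1.7)
        prior, post, _ = eb_moderate(s2, 1e4)
        assert prior.d0 == pytest.approx(1e6)
        np.testing.assert_allclose(post, 1.7, rtol=1e-3)

    def test_huge_prior_df_pins_posterior_at_prior_variance(self):
        # nearly-identical variances: d0 -> cap, posterior -> s0^2 for all
        s2 = 2.0 + 1e-9 * np.arange(5)
        prior, post, _ = eb_moderate(s2, 4.0)
        np.testing.assert_allclose(post, prior.s0_squared, rtol=1e-6)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(6)
        s2 = rng.uniform(0.5, 3.0, 50)
        prior, post, _ = eb_moderate(s2, 8.0)
        lo = np.minimum(s2, prior.s0_squared) - 1e-12
        hi = np.maximum(s2, prior.s0_squared) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()

    def test_prior_recovery(self):
        """Variances drawn from a scaled-inverse-chi-square prior with d0=4,
        s0^2=2 are recovered by moment matching."""
        rng = np.random.default_rng(7)
        d0, s0sq, m = 4.0, 2.0, 500
        s2 = s0sq * d0 / rng.chisquare(d0, size=m)
        prior, _, _ = eb_moderate(s2, 1e4)
        assert 3.0 <= prior.d0 <= 5.0
        assert 1.8 <= prior.s0_squared <= 2.2

    def test_trigamma_inverse_round_trip(self):
        for y in [1e-4, 0.01, 0.5, 3.0, 100.0]:
            x = _trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_moderated_p_uniform_under_null(self):
        """Global null, independent Gaussian errors: moderated-t p-values are
        uniform (pooled over many small datasets)."""
        rng = np.random.default_rng(8)
        n, m, n_datasets = 30, 250, 40
        pvals = []
        from scipy.stats import t as t_dist

        for _ in range(n_datasets):
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            betas, unscaled, s2 = np.empty(m), np.empty(m), np.empty(m)
            for j in range(m):
                f = fit_weighted_lm(rng.standard_normal(n), X)
                betas[j], unscaled[j], s2[j] = f.beta[1], f.xtx_inv[1, 1], f.sigma2
            _, post_var, post_df = eb_moderate(s2, float(n - 2))
            t = betas / np.sqrt(post_var * unscaled)
            pvals.append(2 * t_dist.sf(np.abs(t), np.minimum(post_df, 1e6)))
        p = np.concatenate(pvals)
        assert kstest(p, "uniform").pvalue > 0.01


class TestWeightedLMM:
    def test_zero_variance_component_degenerates_to_lm(self):
        rng = np.random.default_rng(9)
        n = 80
        groups = rng.integers(8, size=n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.5, 2.0, n)
        y = X @ [1.0, 0.5] + rng.normal(0, 1, n)  # no group effect
        f_lmm = fit_weighted_lmm(y, X, {"g": groups}, w)
        f_lm = fit_weighted_lm(y, X, w)
        np.testing.assert_allclose(f_lmm.beta, f_lm.beta, atol=1e-5)
        assert f_lmm.singular

    def test_matches_statsmodels_reml_at_unit_weights(self):
        """Independent REML implementation agrees on fixed effects."""
        rng = np.random.default_rng(10)
        n, g = 150, 15
        groups = rng.integers(g, size=n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.4] + rng.normal(0, 0.8, g)[groups] + rng.normal(0, 1, n)
        mine = fit_weighted_lmm(y, X, {"g": groups})
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        np.testing.assert_allclose(mine.beta, ref.fe_params, atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(mine.Sigma)), ref.bse_fe, atol=1e-3
        )
        assert abs(mine.varcomp["g"] - np.asarray(ref.cov_re)[0, 0]) < 1e-3

    def test_icc_recovered_single_fit(self):
        rng = np.random.default_rng(11)
        n, g = 400, 20
        groups = np.repeat(np.arange(g), n // g)
        X = np.ones((n, 1))
        y = rng.normal(0, 1, g)[groups] + rng.normal(0, 1, n)
        fit = fit_weighted_lmm(y, X, {"g": groups})
        icc = fit.varcomp["g"] / (fit.varcomp["g"] + fit.sigma2)
        assert 0.3 < icc < 0.7


class TestLMMCrossCovariance:
    def test_self_block_is_sigma(self):
        rng = np.random.default_rng(12)
        n = 60
        groups = rng.integers(6, size=n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.normal(0, 1, 6)[groups] + rng.normal(0, 1, n)
        fit = fit_weighted_lmm(y, X, {"g": groups})
        np.testing.assert_allclose(lmm_cross_covariance(fit, fit), fit.Sigma, atol=1e-12)

    def test_equal_fits_on_same_data_give_sigma(self):
        rng = np.random.default_rng(13)
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        f1 = fit_weighted_lm(y, X)
        f2 = fit_weighted_lm(y, X)
        np.testing.assert_allclose(lmm_cross_covariance(f1, f2), f1.Sigma, atol=1e-10)

    def test_shared_weights_match_fixed_effects_formula(self):
        """With weights shared across responses the correlation-of-residuals
        form coincides with the weighted multivariate-regression covariance."""
        rng = np.random.default_rng(14)
        n, m = 50, 4
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.3, 3.0, n)
        Y = rng.standard_normal((n, m))
        fits = [fit_weighted_lm(Y[:, j], X, w) for j in range(m)]
        cov = cross_covariance(fits, 1)
        for i in range(m):
            for j in range(m):
                block = lmm_cross_covariance(fits[i], fits[j])
                assert block[1, 1] == pytest.approx(cov.omega[i, j], abs=1e-8)


class TestFitComposition:
    def test_weight_scale_invariance_through_pipeline(self, baseline_dataset):
        cres = crumblr(baseline_dataset.counts)
        f1 = fit_composition(cres, baseline_dataset.metadata, "~ x", "x")
        scaled = cres
        scaled.weights.iloc[:, :] = cres.weights.to_numpy() * 42.0
        f2 = fit_composition(scaled, baseline_dataset.metadata, "~ x", "x")
        np.testing.assert_allclose(f1.table["estimate"], f2.table["estimate"], atol=1e-8)
        np.testing.assert_allclose(f1.table["p_value"], f2.table["p_value"], atol=1e-8)

    def test_detects_simulated_effect(self, baseline_dataset):
        cres = crumblr(baseline_dataset.counts)
        fit = fit_composition(cres, baseline_dataset.metadata, "~ x", "x")
        affected = baseline_dataset.truth.index[baseline_dataset.truth["affected"]][0]
        assert fit.table.loc[affected, "fdr"] < 0.05
        assert fit.table.loc[affected, "estimate"] > 0

    def test_random_term_formula_runs_mixed_model(self):
        from crumblr import SimulationConfig, simulate

        ds = simulate(SimulationConfig(n_samples=60, n_clusters=5,
                                       batch_count=6, batch_variance_fraction=0.2, seed=5))
        cres = crumblr(ds.counts)
        fit = fit_composition(cres, ds.metadata, "~ x + (1|batch)", "x")
        assert fit.mixed
        assert np.isfinite(fit.table["p_value"]).all()
        cov = fit.coef_covariance(["C1", "C2", "C3"])
        assert cov.omega.shape == (3, 3)
        assert (np.diag(cov.omega) > 0).all()
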