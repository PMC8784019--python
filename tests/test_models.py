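"""Estimator correctness against independent oracles.

The dummy-coded LM is checked against an explicit normal-equations solve
and statsmodels OLS; the profiled-REML LMM is checked against a dense
linear-algebra evaluation of the restricted deviance, an exhaustive grid
search, closed-form balanced-ANOVA estimators, and the lme4 reference
implementation (via Rscript).
"""

import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from fewlevels import (
    RandomInterceptLMM,
    ScenarioConfig,
    SimDataset,
    child_rng,
    fit_lm,
    fit_lmm,
    gen_dataset,
    reml_criterion,
    slopes_at_infinite_variance,
)

SEEDS = [0, 1, 2, 3, 4]


def make_dataset(seed, n_obs=120, n_levels=10, **kwargs):
    cfg = ScenarioConfig(n_obs=n_obs, n_levels=n_levels, **kwargs)
    return gen_dataset(cfg, child_rng(seed, n_obs, n_levels, 0))


def lm_design(ds):
    dummies = (ds.group[:, None] == np.arange(2, ds.n_levels + 1)[None, :]).astype(float)
    return np.column_stack([np.ones(ds.n_obs), ds.x1, ds.x2, dummies])


def dense_reml_criterion(ds, theta):
    """Brute-force restricted deviance with explicit dense matrices."""
    n = ds.n_obs
    Z = (ds.group[:, None] == np.arange(1, ds.n_levels + 1)[None, :]).astype(float)
    X = np.column_stack([np.ones(n), ds.x1, ds.x2])
    V = np.eye(n) + theta**2 * Z @ Z.T
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ ds.y)
    r = ds.y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetA = np.linalg.slogdet(A)
    return logdetV + logdetA + (n - 3) * np.log(r @ Vinv @ r)


class TestDummyCodedLM:
    def test_exact_interpolation_of_noise_free_data(self):
        ds = make_dataset(
            0, n_obs=30, n_levels=3, beta0=0.0, beta2=0.0, sigma2_site=0.0, sigma2_resid=0.0
        )
        fit = fit_lm(ds)
        assert fit.slopes[0].estimate == pytest.approx(2.0, abs=1e-10)
        assert fit.sigma2_resid_hat == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_normal_equations_oracle(self, seed):
        ds = make_dataset(seed)
        fit = fit_lm(ds)
        X = lm_design(ds)
        beta = np.linalg.solve(X.T @ X, X.T @ ds.y)
        assert fit.slopes[0].estimate == pytest.approx(beta[1], abs=1e-8)
        assert fit.slopes[1].estimate == pytest.approx(beta[2], abs=1e-8)
        alphas = beta[0] + np.concatenate([[0.0], beta[3:]])
        np.testing.assert_allclose(fit.group_effects, alphas, atol=1e-8)
        resid = ds.y - X @ beta
        df = ds.n_obs - X.shape[1]
        assert fit.df_resid == df
        assert fit.sigma2_resid_hat == pytest.approx(resid @ resid / df, rel=1e-10)

    def test_matches_statsmodels_ols(self, dataset):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_lm(dataset)
        res = sm.OLS(dataset.y, lm_design(dataset)).fit()
        assert fit.slopes[0].estimate == pytest.approx(res.params[1], abs=1e-10)
        assert fit.slopes[0].se == pytest.approx(res.bse[1], rel=1e-10)
        lo, hi = res.conf_int(alpha=0.05)[1]
        assert fit.slopes[0].ci_low == pytest.approx(lo, rel=1e-10)
        assert fit.slopes[0].ci_high == pytest.approx(hi, rel=1e-10)

    def test_t_interval_width(self, small_dataset):
        fit = fit_lm(small_dataset, alpha=0.05, interval="t")
        e = fit.slopes[0]
        crit = stats.t.ppf(0.975, fit.df_resid)
        assert e.ci_high - e.ci_low == pytest.approx(2 * crit * e.se, rel=1e-12)

    def test_rank_deficiency_names_offending_column(self, dataset):
        bad = SimDataset(
            y=dataset.y,
            x1=dataset.x1,
            x2=dataset.x1.copy(),  # perfectly collinear
            group=dataset.group,
            true_site_effects=dataset.true_site_effects,
            config=dataset.config,
        )
        with pytest.raises(np.linalg.LinAlgError, match="beta"):
            fit_lm(bad)


class TestREMLCriterion:
    @pytest.mark.parametrize("seed", SEEDS[:3])
    def test_matches_dense_oracle(self, seed):
        ds = make_dataset(seed, n_obs=60, n_levels=5)
        for theta in (0.0, 0.1, 0.7, 1.0, 3.0, 10.0):
            assert reml_criterion(ds, theta) == pytest.approx(
                dense_reml_criterion(ds, theta), abs=1e-8
            )

    def test_theta_zero_is_identity_v_criterion(self, dataset):
        # V = I: the criterion reduces to the OLS-based restricted form of
        # the pooled model
        n = dataset.n_obs
        X = np.column_stack([np.ones(n), dataset.x1, dataset.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ dataset.y)
        r = dataset.y - X @ beta
        _, logdetA = np.linalg.slogdet(X.T @ X)
        expected = logdetA + (n - 3) * np.log(r @ r)
        assert reml_criterion(dataset, 0.0) == pytest.approx(expected, abs=1e-8)

    def test_finite_and_continuous_on_grid(self, small_dataset):
        thetas = np.linspace(0, 10, 401)
        vals = np.array([reml_criterion(small_dataset, t) for t in thetas])
        assert np.all(np.isfinite(vals))
        # no jumps anywhere near the scale of the criterion's total range
        assert np.max(np.abs(np.diff(vals))) < 0.05 * (vals.max() - vals.min()) + 1e-6

    def test_negative_theta_rejected(self, dataset):
        with pytest.raises(ValueError, match="nonnegative"):
            reml_criterion(dataset, -0.5)


class TestFitLMM:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_optimum_dominates_fine_grid(self, seed):
        ds = make_dataset(seed, n_obs=60, n_levels=5)
        fit = fit_lmm(ds)
        grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e3, 1000)])
        grid_best = min(reml_criterion(ds, t) for t in grid)
        assert reml_criterion(ds, fit.theta_hat) <= grid_best + 1e-9

    def test_variance_component_identity(self, dataset):
        fit = fit_lmm(dataset)
        assert fit.sigma2_site_hat == pytest.approx(
            fit.theta_hat**2 * fit.sigma2_resid_hat, rel=1e-12
        )

    def test_no_between_group_signal_is_singular(self):
        # identical within-group response patterns: group means are all
        # equal, so the profiled deviance is minimised at the boundary
        g, m = 4, 5
        groups = np.repeat(np.arange(1, g + 1), m)
        y = np.tile(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), g) + 10.0
        fit = RandomInterceptLMM(y, np.ones((g * m, 1)), groups, ["intercept"]).fit()
        assert fit.theta_hat == 0.0
        assert fit.singular

    def test_singular_tol_is_configurable(self, dataset):
        fit = fit_lmm(dataset, singular_tol=1e-4)
        assert not fit.singular
        assert fit_lmm(dataset, singular_tol=10.0).singular
        with pytest.raises(ValueError):
            fit_lmm(dataset, singular_tol=0.0)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_lme4_reference(self, seed, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        ds = make_dataset(seed)
        path = tmp_path / "d.csv"
        ds.to_csv(path)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{path}');"
            "m <- lmer(y ~ x1 + x2 + (1|group), data=d, REML=TRUE,"
            " control=lmerControl(optimizer='bobyqa', optCtrl=list(rhoend=1e-12)));"
            "vc <- as.data.frame(VarCorr(m));"
            "cat(fixef(m), vc$vcov, getME(m,'theta'))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        fit = fit_lmm(ds)
        ours = np.array(
            [
                fit.intercept.estimate,
                fit.slopes[0].estimate,
                fit.slopes[1].estimate,
                fit.sigma2_site_hat,
                fit.sigma2_resid_hat,
                fit.theta_hat,
            ]
        )
        np.testing.assert_allclose(ours, ref, rtol=1e-4)

    @pytest.mark.parametrize("seed", SEEDS[:3])
    def test_matches_statsmodels_mixedlm(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        ds = make_dataset(seed)
        fit = fit_lmm(ds)
        X = np.column_stack([np.ones(ds.n_obs), ds.x1, ds.x2])
        res = sm.MixedLM(ds.y, X, groups=ds.group).fit(reml=True)
        ours_fe = [fit.intercept.estimate, fit.slopes[0].estimate, fit.slopes[1].estimate]
        # tolerance reflects the reference optimizer's own convergence
        np.testing.assert_allclose(ours_fe, res.fe_params, rtol=5e-4)
        assert fit.sigma2_site_hat == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), rel=5e-4)
        assert fit.sigma2_resid_hat == pytest.approx(res.scale, rel=5e-4)

    def test_balanced_design_matches_anova_closed_form(self):
        # balanced one-way layout, intercept only: REML equals the ANOVA
        # estimators sigma2_within = MSW, sigma2_between = (MSB - MSW)/m
        rng = np.random.default_rng(3)
        g, m = 6, 5
        groups = np.repeat(np.arange(1, g + 1), m)
        y = rng.normal(0, 1, g * m) + np.repeat(rng.normal(0, 1.2, g), m)
        fit = RandomInterceptLMM(y, np.ones((g * m, 1)), groups, ["intercept"]).fit()
        ym = y.reshape(g, m)
        msb = m * np.sum((ym.mean(axis=1) - y.mean()) ** 2) / (g - 1)
        msw = np.sum((ym - ym.mean(axis=1, keepdims=True)) ** 2) / (g * (m - 1))
        assert fit.sigma2_resid_hat == pytest.approx(msw, rel=1e-6)
        assert fit.sigma2_site_hat == pytest.approx(max((msb - msw) / m, 0.0), rel=1e-6)

    def test_covariance_symmetric_psd(self, dataset):
        cov = fit_lmm(dataset).cov_params
        np.testing.assert_allclose(cov, cov.T, atol=1e-14)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12

    def test_ses_shrink_with_sample_size(self):
        ses = {}
        for n in (30, 120):
            vals = [
                fit_lmm(make_dataset(s, n_obs=n, n_levels=3)).slopes[0].se for s in range(40)
            ]
            ses[n] = np.mean(vals)
        assert ses[120] < ses[30]


class TestPoolingLimits:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_infinite_variance_limit_equals_lm(self, seed):
        ds = make_dataset(seed, n_obs=60, n_levels=5)
        b1, b2 = slopes_at_infinite_variance(ds)
        lm = fit_lm(ds)
        assert b1 == pytest.approx(lm.slopes[0].estimate, abs=1e-8)
        assert b2 == pytest.approx(lm.slopes[1].estimate, abs=1e-8)

    def test_gls_at_huge_theta_approaches_limit(self, dataset):
        model = RandomInterceptLMM(
            dataset.y,
            np.column_stack([np.ones(dataset.n_obs), dataset.x1, dataset.x2]),
            dataset.group,
        )
        beta, *_ = model._solve(1e6)
        b1, b2 = slopes_at_infinite_variance(dataset)
        assert beta[1] == pytest.approx(b1, abs=1e-4)
        assert beta[2] == pytest.approx(b2, abs=1e-4)

    def test_theta_zero_equals_pooled_ols(self, dataset):
        model = RandomInterceptLMM(
            dataset.y,
            np.column_stack([np.ones(dataset.n_obs), dataset.x1, dataset.x2]),
            dataset.group,
        )
        beta, *_ = model._solve(0.0)
        X = np.column_stack([np.ones(dataset.n_obs), dataset.x1, dataset.x2])
        pooled = np.linalg.solve(X.T @ X, X.T @ dataset.y)
        np.testing.assert_allclose(beta, pooled, atol=1e-12)
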