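import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

import dynocc as dy
from dynocc.fit import _CovariateImputer
from dynocc.model import CovariateSet, ModelParams, StudyDesign

from conftest import make_simple_covs, simple_true_params


class TestMLE:
    def test_recovers_intercept_occupancy_with_perfect_detection(self):
        # theta = p = 1 makes psi directly observable; check 3-SE recovery
        design = StudyDesign(800, 2, 2, 1)
        N = design.n_units
        covs = CovariateSet(
            np.ones((N, 1)), np.empty((N, 0, 1)), np.ones((N, 2, 1, 1))
        )
        true = ModelParams([dy.logit(0.8)], [0.0], [0.0], [8.0], [0.999])
        real = dy.simulate_realization(true, covs, design, rng_seed=31)
        res = dy.fit_mle(real.y, covs, design)
        psi_hat = expit(res.estimates[0])
        se_psi = res.se[0] * psi_hat * (1 - psi_hat)
        assert abs(psi_hat - 0.8) < 3 * max(se_psi, 0.02)

    def test_zero_detections_flagged_boundary(self):
        design = StudyDesign(30, 2, 3, 2)
        covs = CovariateSet(
            np.ones((30, 1)), np.ones((30, 1, 1)), np.ones((30, 2, 2, 1))
        )
        y = np.zeros(design.shape_y)
        res = dy.fit_mle(y, covs, design)
        assert not res.converged
        assert res.warnings

    def test_single_year_matches_direct_static_optimum(self):
        """T=1 intercept-only fit agrees with a direct 1-d optimization of
        the static multi-scale formula at fixed theta and p."""
        design = StudyDesign(120, 3, 3, 1)
        N = design.n_units
        covs = CovariateSet(np.ones((N, 1)), np.empty((N, 0, 1)), np.ones((N, 3, 1, 1)))
        true = ModelParams([dy.logit(0.7)], [0.0], [0.0], [dy.logit(0.8)], [0.7])
        real = dy.simulate_realization(true, covs, design, rng_seed=5)
        res = dy.fit_mle(real.y, covs, design, start=true)
        # layout: [beta, eta, delta_coef, alpha, logit_p]
        theta_hat = expit(res.estimates[3])
        p_hat = expit(res.estimates[4])

        from _reference import static_multiscale_loglik

        def neg(x):
            psi = np.full(N, expit(x))
            th = np.full((N, 3), theta_hat)
            return -static_multiscale_loglik(real.y[..., 0], psi, th, p_hat)

        direct = minimize_scalar(neg, bounds=(-5, 5), method="bounded").x
        assert expit(direct) == pytest.approx(expit(res.estimates[0]), abs=1e-4)

    def test_interval_brackets_estimate(self, calibration_design):
        covs = make_simple_covs(calibration_design, seed=1)
        true = simple_true_params(calibration_design.n_years)
        real = dy.simulate_realization(true, covs, calibration_design, rng_seed=2)
        res = dy.fit_mle(real.y, covs, calibration_design)
        assert (res.ci_lower <= res.estimates).all()
        assert (res.estimates <= res.ci_upper).all()
        assert res.converged


class TestMCMC:
    def test_same_seed_identical_draws(self, calibration_design):
        design = StudyDesign(20, 3, 3, 3)
        covs = make_simple_covs(design, seed=4)
        true = simple_true_params(design.n_years)
        real = dy.simulate_realization(true, covs, design, rng_seed=6)
        kw = dict(n_samples=300, burn_in=100, chains=2, rng_seed=42)
        a = dy.fit_mcmc(real.y, covs, design, **kw)
        b = dy.fit_mcmc(real.y, covs, design, **kw)
        assert np.array_equal(a.draws, b.draws)

    def test_rejects_bad_sampling_plan(self, calibration_design):
        covs = make_simple_covs(calibration_design)
        y = np.zeros(calibration_design.shape_y)
        with pytest.raises(ValueError):
            dy.fit_mcmc(y, covs, calibration_design, n_samples=100, burn_in=100)
        with pytest.raises(ValueError):
            dy.fit_mcmc(y, covs, calibration_design, n_samples=100, burn_in=10, chains=0)

    def test_prior_only_run_recovers_uniform_p(self):
        design = StudyDesign(5, 2, 3, 2)
        covs = make_simple_covs(design, seed=1)
        y = np.full(design.shape_y, np.nan)  # nothing surveyed
        res = dy.fit_mcmc(y, covs, design, n_samples=8000, burn_in=2000, chains=2, rng_seed=9)
        p_draws = expit(res.draw_matrix()[:, -design.n_years :])
        assert np.allclose(p_draws.mean(axis=0), 0.5, atol=0.05)
        assert np.allclose(p_draws.std(axis=0), np.sqrt(1 / 12), atol=0.03)
        # a coefficient's prior: Normal(0, sd 10)
        beta_draws = res.draw_matrix()[:, 0]
        assert abs(beta_draws.mean()) < 2.0
        assert 6.5 < beta_draws.std() < 13.5

    def test_posterior_matches_mle_on_informative_data(self, calibration_design):
        covs = make_simple_covs(calibration_design, seed=8)
        true = simple_true_params(calibration_design.n_years)
        real = dy.simulate_realization(true, covs, calibration_design, rng_seed=10)
        mle = dy.fit_mle(real.y, covs, calibration_design)
        mcmc = dy.fit_mcmc(
            real.y, covs, calibration_design, n_samples=2500, burn_in=1000,
            chains=2, rng_seed=11,
        )
        post_sd = mcmc.draw_matrix().std(axis=0)
        comb = np.sqrt(post_sd**2 + np.where(np.isfinite(mle.se), mle.se, 0) ** 2)
        assert (np.abs(mcmc.estimates - mle.estimates) < 2.5 * comb).all()


class TestImputation:
    def test_no_missing_is_identity(self, small_design):
        covs = dy.simulate_covariates(small_design, rng_seed=1)
        out, log = dy.impute_missing_covariates(covs)
        assert log["n_missing_cells"] == 0
        assert out is covs

    def test_degenerate_empirical_distribution(self, small_design):
        covs = dy.simulate_covariates(small_design, rng_seed=2)
        col = covs.local_names.index("grass_cover")
        covs.w_local[..., col] = 0.4
        covs.w_local[0, 0, 0, col] = np.nan
        out, log = dy.impute_missing_covariates(covs, rng=3)
        assert out.w_local[0, 0, 0, col] == 0.4
        assert log["n_missing_cells"] == 1

    def test_binned_column_imputed_from_observed_bins(self, small_design):
        covs = dy.simulate_covariates(small_design, rng_seed=4)
        col = covs.local_names.index("grass_cover")
        observed = covs.w_local[..., col].copy()
        covs.w_local[0, :, 0, col] = np.nan
        out, _ = dy.impute_missing_covariates(covs, rng=5)
        filled = out.w_local[0, :, 0, col]
        assert np.isin(filled, np.unique(observed[np.isfinite(observed)])).all()

    def test_quadratic_column_recomputed(self, small_design):
        covs = dy.simulate_covariates(small_design, rng_seed=6)
        lin = covs.local_names.index("grass_height")
        sq = covs.local_names.index("grass_height_sq")
        covs.w_local[1, 2, 1, lin] = np.nan
        covs.w_local[1, 2, 1, sq] = np.nan
        out, _ = dy.impute_missing_covariates(covs, rng=7)
        assert out.w_local[1, 2, 1, sq] == pytest.approx(out.w_local[1, 2, 1, lin] ** 2)

    def test_entirely_missing_column_rejected(self, small_design):
        covs = dy.simulate_covariates(small_design, rng_seed=8)
        covs.w_local[..., covs.local_names.index("shrub_cover")] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            dy.impute_missing_covariates(covs)

    def test_low_missingness_barely_shifts_posterior(self):
        """2% missing station covariates: posterior means within 1 posterior
        SD of the complete-data fit."""
        design = StudyDesign(60, 4, 3, 3)
        covs = make_simple_covs(design, seed=12)
        true = simple_true_params(design.n_years)
        real = dy.simulate_realization(true, covs, design, rng_seed=13)
        kw = dict(n_samples=1500, burn_in=600, chains=1, rng_seed=14)
        full = dy.fit_mcmc(real.y, covs, design, **kw)
        holed = CovariateSet(
            covs.x_init.copy(), covs.x_dyn.copy(), covs.w_local.copy()
        )
        rng = np.random.default_rng(15)
        mask = rng.random(design.n_units * design.n_stations * design.n_years) < 0.02
        flat = holed.w_local[..., 1].reshape(-1)
        flat[mask] = np.nan
        miss = dy.fit_mcmc(real.y, holed, design, **kw)
        sd = full.draw_matrix().std(axis=0)
        assert (np.abs(full.estimates - miss.estimates) < np.maximum(sd, 0.05)).all()


class TestDiagnostics:
    def _result_from_draws(self, draws):
        P = draws.shape[-1]
        structure = dy.ParamStructure(1, 1, 1, P - 4)
        pooled = draws.reshape(-1, P)
        est = pooled.mean(axis=0)
        return dy.FitResult(
            method="mcmc", structure=structure,
            param_names=[f"par{i}" for i in range(P)],
            estimates=est,
            ci_lower=np.quantile(pooled, 0.025, axis=0),
            ci_upper=np.quantile(pooled, 0.975, axis=0),
            draws=draws,
        )

    def test_iid_draws_rhat_near_one_and_ess_near_n(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((2, 1000, 5))
        rep = dy.diagnostics(self._result_from_draws(draws))
        assert np.allclose(rep["rhat"], 1.0, atol=0.05)
        assert (np.abs(rep["ess"] - 2000) < 0.2 * 2000).all()
        assert not rep["flagged"].any()

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500, 5))
        draws[1, :, 0] += 10.0
        rep = dy.diagnostics(self._result_from_draws(draws))
        assert rep["rhat"].iloc[0] > 1.1
        assert rep["flagged"].iloc[0]

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((1, 400, 5))
        rep = dy.diagnostics(self._result_from_draws(draws))
        assert rep["rhat"].isna().all()
        assert not rep["flagged"].any()

    def test_requires_draws(self, calibration_design):
        covs = make_simple_covs(calibration_design)
        structure = dy.ParamStructure.from_covs(covs, calibration_design)
        vec = np.zeros(structure.size)
        res = dy.FitResult("mle", structure, structure.names(), vec, vec, vec)
        with pytest.raises(ValueError):
            dy.diagnostics(res)
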