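import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import expit, logit

import wastingmap as wm
from wastingmap.inference import (
    ModelConfig,
    _inner_newton,
    _prior_precision,
    build_structure,
    binomial_loglik,
    laplace_fit,
    mcmc_oracle,
    predict_prevalence,
    predict_prevalence_at_points,
    seasonal_effect_estimates,
)


class TestBinomialLoglik:
    def test_symmetric_stationary_point(self):
        n = np.full(10, 40.0)
        _, grad, w = binomial_loglik(np.zeros(10), n / 2, n)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)
        assert np.all(w > 0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 1.5, 20)
        n = rng.integers(10, 100, 20).astype(float)
        y = rng.binomial(n.astype(int), 0.3).astype(float)
        val, grad, _ = binomial_loglik(eta, y, n)
        h = 1e-6
        for j in range(0, 20, 5):
            e = np.zeros(20)
            e[j] = h
            num = (
                binomial_loglik(eta + e, y, n)[0]
                - binomial_loglik(eta - e, y, n)[0]
            ) / (2 * h)
            assert grad[j] == pytest.approx(num, abs=1e-4)

    def test_concavity(self):
        rng = np.random.default_rng(1)
        eta = rng.normal(0, 3, 50)
        n = rng.integers(1, 200, 50).astype(float)
        _, _, w = binomial_loglik(eta, np.zeros(50), n)
        assert np.all(w >= 0)  # Hessian diag is -w <= 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_loglik([0.0], [5.0], [3.0])


@pytest.fixture(scope="module")
def tiny_fit_inputs(region, covariates):
    locs = wm.sample_cluster_locations(region, 50, seed=51)
    params = wm.TrueParameters(
        beta={}, spatial_sd=0.3, cluster_sd=0.0, spatial_range=60.0
    )
    df = wm.simulate_wasting_data(
        region, locs, covariates, params,
        years=(2007,), n_per_cluster=(40, 60), seed=52,
    )
    cfg = ModelConfig(
        model=1, years=(2007,), covariates=(), mesh_edge_km=60.0,
        mesh_buffer_km=50.0, use_cluster_effect=False,
    )
    return df, cfg


class TestLaplace:
    def test_gaussian_conjugate_closed_form(self, tiny_fit_inputs):
        df, cfg = tiny_fit_inputs
        gauss_cfg = ModelConfig(
            **{**cfg.__dict__, "likelihood": "gaussian", "gaussian_noise_sd": 1.0}
        )
        st = build_structure(df, gauss_cfg)
        Q, _ = _prior_precision(st, st.psi_init)
        mode, _, _, ok = _inner_newton(st, Q)
        H = (Q + st.A.T @ st.A).tocsc()
        closed = sp.linalg.spsolve(H, st.A.T @ st.y)
        assert ok
        np.testing.assert_allclose(mode, closed, atol=1e-8)

    def test_newton_flags_convergence(self, tiny_fit_inputs):
        df, cfg = tiny_fit_inputs
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 30, "restarts": 0}, seed=0
        )
        assert fit.converged
        assert fit.fixed_summary.iloc[0]["name"] == "intercept"
        odds = fit.fixed_summary.iloc[0]["odds"]
        assert odds == pytest.approx(
            np.exp(fit.fixed_summary.iloc[0]["mean"])
        )

    def test_marginal_sds_nonnegative(self, tiny_fit_inputs):
        df, cfg = tiny_fit_inputs
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 20, "restarts": 0}, seed=0
        )
        sds = fit.marginal_sd([0, 1, 2])
        assert np.all(sds >= 0)


class TestMcmcOracle:
    def test_prior_only_centred_at_zero(self, region, covariates):
        # clusters with zero children examined contribute no likelihood
        locs = wm.sample_cluster_locations(region, 20, seed=61)
        params = wm.TrueParameters(beta={}, spatial_sd=0.4, cluster_sd=0.0)
        df = wm.simulate_wasting_data(
            region, locs, covariates, params, years=(2007,), seed=62
        )
        df["n_examined"] = 0
        df["n_wasted"] = 0
        cfg = ModelConfig(
            model=1, years=(2007,), covariates=(), mesh_edge_km=70.0,
            mesh_buffer_km=50.0, use_cluster_effect=False,
        )
        st = build_structure(df, cfg)
        out = mcmc_oracle(df, cfg, st.psi_init, n_iter=3000, seed=63)
        z = np.abs(out["mean"]) / np.maximum(out["se"], 1e-12)
        assert np.max(z) < 4.0

    def test_se_scales_with_iterations(self, tiny_fit_inputs):
        df, cfg = tiny_fit_inputs
        st = build_structure(df, cfg)
        a = mcmc_oracle(df, cfg, st.psi_init, n_iter=1500, seed=64)
        b = mcmc_oracle(df, cfg, st.psi_init, n_iter=3000, seed=65)
        ratio = np.median(a["se"] / b["se"])
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.30)

    def test_dimension_guard(self, region, covariates):
        locs = wm.sample_cluster_locations(region, 30, seed=66)
        params = wm.TrueParameters(beta={})
        df = wm.simulate_wasting_data(region, locs, covariates, params, seed=67)
        cfg = ModelConfig(model=1, mesh_edge_km=8.0, mesh_buffer_km=80.0)
        st = build_structure(df, cfg)
        assert st.layout.total_dim > 2000
        with pytest.raises(ValueError, match="guard"):
            mcmc_oracle(df, cfg, st.psi_init, n_iter=10, seed=0)


class TestPrediction:
    def test_flat_latent_gives_constant_prevalence(self, tiny_fit_inputs, region, covariates):
        df, cfg = tiny_fit_inputs
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 10, "restarts": 0}, seed=0
        )
        fit.mode[:] = 0.0
        fit.mode[0] = logit(0.2)
        pred = predict_prevalence(
            fit, region.empty_grid(), covariates, [(2007, "Gu")], with_sd=False
        )
        vals = pred.grids[(2007, "Gu")].values
        np.testing.assert_allclose(vals[np.isfinite(vals)], 0.2, atol=1e-12)
        assert pred.n_masked == 0

    def test_covariate_monotonicity(self, region, covariates):
        # positive fitted beta: raising the covariate raises prevalence
        locs = wm.sample_cluster_locations(region, 40, seed=71)
        params = wm.TrueParameters(
            beta={"rainfall": 0.5}, spatial_sd=0.0, cluster_sd=0.0
        )
        df = wm.simulate_wasting_data(
            region, locs, covariates, params, years=(2007,), seed=72
        )
        cfg = ModelConfig(
            model=1, years=(2007,), covariates=("rainfall",),
            mesh_edge_km=60.0, mesh_buffer_km=50.0,
        )
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 40, "restarts": 0}, seed=0
        )
        beta_hat = fit.fixed_summary.set_index("name").loc["rainfall", "mean"]
        assert beta_hat > 0
        base = predict_prevalence(
            fit, region.empty_grid(), covariates, [(2007, "Gu")], with_sd=False
        ).grids[(2007, "Gu")].values
        shifted_covs = dict(covariates)
        shifted_covs["rainfall"] = covariates["rainfall"].with_values(
            covariates["rainfall"].values + 10.0
        )
        up = predict_prevalence(
            fit, region.empty_grid(), shifted_covs, [(2007, "Gu")], with_sd=False
        ).grids[(2007, "Gu")].values
        assert np.all(up > base)

    def test_high_n_cluster_dominates_prediction(self, region, covariates):
        locs = wm.sample_cluster_locations(region, 12, seed=73)
        params = wm.TrueParameters(beta={}, spatial_sd=0.2, cluster_sd=0.0)
        df = wm.simulate_wasting_data(
            region, locs, covariates, params, years=(2007,), seed=74
        )
        df.loc[0, "n_examined"] = 10_000
        df.loc[0, "n_wasted"] = 3_000
        cfg = ModelConfig(
            model=1, years=(2007,), covariates=(), mesh_edge_km=50.0,
            mesh_buffer_km=50.0, use_cluster_effect=False,
        )
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 40, "restarts": 0}, seed=0
        )
        pred = predict_prevalence_at_points(fit, df.iloc[[0]])
        assert pred[0] == pytest.approx(0.3, abs=0.02)

    def test_prevalence_in_unit_interval(self, tiny_fit_inputs, region, covariates):
        df, cfg = tiny_fit_inputs
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 20, "restarts": 0}, seed=0
        )
        pred = predict_prevalence(
            fit, region.empty_grid(), covariates,
            [(2007, s) for s in wm.SEASONS],
        )
        for g in pred.grids.values():
            v = g.values[np.isfinite(g.values)]
            assert np.all((v > 0) & (v < 1))
        for g in pred.sd_grids.values():
            v = g.values[np.isfinite(g.values)]
            assert np.all(v >= 0)


@pytest.fixture(scope="module")
def model2_fit(region, covariates):
    locs = wm.sample_cluster_locations(region, 200, seed=81)
    params = wm.TrueParameters(
        beta={}, spatial_sd=0.2, cluster_sd=0.2,
        seasonal_offsets=(0.5, -0.5, 0.5, -0.5),
    )
    df = wm.simulate_wasting_data(
        region, locs, covariates, params, n_per_cluster=(50, 90), seed=82
    )
    cfg = ModelConfig(
        model=2, covariates=(), mesh_edge_km=60.0, mesh_buffer_km=60.0
    )
    return laplace_fit(
        df, cfg, optimizer_config={"maxiter": 60, "restarts": 0}, seed=0
    )


class TestSeasonalEffects:
    def test_recovers_seasonal_signs(self, model2_fit):
        seas = seasonal_effect_estimates(model2_fit)
        signs = np.sign(seas["mean_log_odds"].to_numpy())
        np.testing.assert_array_equal(signs, [1, -1, 1, -1])

    def test_sum_to_zero_constraint(self, model2_fit):
        seas = seasonal_effect_estimates(model2_fit)
        assert abs(seas["mean_log_odds"].sum()) < 1e-8

    def test_model1_fit_rejected(self, tiny_fit_inputs):
        df, cfg = tiny_fit_inputs
        fit = laplace_fit(
            df, cfg, optimizer_config={"maxiter": 5, "restarts": 0}, seed=0
        )
        with pytest.raises(ValueError, match="model-2"):
            seasonal_effect_estimates(fit)
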