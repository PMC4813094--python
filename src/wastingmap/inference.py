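"""Laplace / empirical-Bayes inference for the latent Gaussian binomial model.

The latent field theta = (intercept, fixed effects, space-time SPDE weights,
seasonal effects, cluster effects) has prior N(0, Q(psi)^-1); each cluster
record contributes a binomial likelihood through a sparse observation matrix
A.  Inference proceeds in two nested loops:

* inner: Newton iterations (with step halving) on the latent field at fixed
  hyperparameters psi — each step is one sparse factorization of
  H = Q + A' W A;
* outer: derivative-free (Nelder-Mead) maximization of the Laplace
  approximation to the marginal posterior of psi.

Two model configurations are supported: model 1 places the AR(2) dynamics
on the combined year-season axis (16 steps over 4 years); model 2 places
AR(2) on years only and adds a shared period-4 seasonal component over the
year-season axis, from which per-season effect sizes are summarized.

An MCMC oracle (preconditioned MALA at fixed psi, dense, test-scale only)
provides an independent check of the Gaussian approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit

from . import precision as prec
from .meshfem import build_mesh, fem_matrices, projection_matrix
from .synthetic import SEASONS, time_index

__all__ = [
    "ModelConfig",
    "PosteriorResult",
    "PrevalenceGrid",
    "binomial_loglik",
    "laplace_fit",
    "mcmc_oracle",
    "predict_prevalence",
    "seasonal_effect_estimates",
]


def binomial_loglik(eta, successes, trials):
    """Binomial log-likelihood with logit link, up to an additive constant.

    Returns (value, gradient, negative-curvature vector w): the Hessian of
    the log-likelihood is diag(-w) with w = n p (1-p) >= 0.
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= trials")
    value = float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
    p = expit(eta)
    grad = y - n * p
    w = n * p * (1.0 - p)
    return value, grad, w


def _gaussian_loglik(eta, y, noise_sd):
    """Test hook: Gaussian observation model with known noise SD."""
    r = np.asarray(y, dtype=float) - eta
    v = 1.0 / noise_sd**2
    value = float(-0.5 * v * np.sum(r**2))
    return value, v * r, np.full(eta.shape, v)


@dataclass
class ModelConfig:
    """Configuration of the space-time model and its priors.

    model 1: AR(2) over the 4 x n_years year-season axis.
    model 2: AR(2) over years; shared period-4 seasonal component over the
    full year-season axis (soft sum-to-zero-per-cycle via the seasonal
    structure matrix plus a weak ridge).
    """

    model: int = 1
    years: tuple = (2007, 2008, 2009, 2010)
    covariates: tuple = ()
    mesh_edge_km: float = 60.0
    mesh_buffer_km: float = 80.0
    basis: str = "intercept"  # "intercept" (stationary) or "linear"
    use_cluster_effect: bool = True
    fixed_prior_prec: float = 1e-4
    seasonal_ridge: float = 1e-4
    hyper_prior_sd: float = 3.0
    likelihood: str = "binomial"  # or "gaussian" (test hook)
    gaussian_noise_sd: float = 1.0
    init_spatial_range: float | None = None  # default: quarter of the domain
    init_spatial_sd: float = 0.5

    def __post_init__(self):
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.basis not in ("intercept", "linear"):
            raise ValueError("basis must be 'intercept' or 'linear'")


@dataclass
class _Structure:
    """Everything about the model that does not depend on psi."""

    config: ModelConfig
    mesh: object
    fem: object
    basis: object
    layout: prec.LatentLayout
    A: sp.csr_matrix
    y: np.ndarray
    n: np.ndarray
    seasonal: object | None
    cov_mean: np.ndarray
    cov_sd: np.ndarray
    cluster_ids: list
    psi_names: list
    psi_init: np.ndarray
    n_seasonal_axis: int  # length of the year-season axis


def _time_axes(config: ModelConfig, year, season):
    """(AR-axis index, seasonal-axis index or None) for one observation."""
    ys = time_index(int(year), season, config.years[0])
    if config.model == 1:
        return ys, None
    return int(year) - config.years[0], ys


def build_structure(observations: pd.DataFrame, config: ModelConfig) -> _Structure:
    obs = observations.reset_index(drop=True)
    locs = obs[["x_km", "y_km"]].to_numpy(dtype=float)
    mesh = build_mesh(locs, max_edge_km=config.mesh_edge_km,
                      buffer_km=config.mesh_buffer_km)
    fem = fem_matrices(mesh)
    basis = (
        prec.intercept_basis(mesh.n_vertices)
        if config.basis == "intercept"
        else prec.linear_basis(mesh.vertices)
    )
    n_v = mesh.n_vertices
    n_years = len(config.years)
    n_t = 4 * n_years if config.model == 1 else n_years
    n_seas_axis = 4 * n_years
    n_seasonal = n_seas_axis if config.model == 2 else 0
    cluster_ids = list(pd.unique(obs["cluster_id"])) if config.use_cluster_effect else []
    layout = prec.LatentLayout(
        n_fixed=len(config.covariates),
        n_spatial=n_v,
        n_time=n_t,
        n_seasonal=n_seasonal,
        n_cluster=len(cluster_ids),
    )

    # covariate standardization (training statistics, reused at prediction)
    if config.covariates:
        Z = obs[list(config.covariates)].to_numpy(dtype=float)
        cov_mean = Z.mean(axis=0)
        cov_sd = np.maximum(Z.std(axis=0), 1e-12)
        Zs = (Z - cov_mean) / cov_sd
    else:
        cov_mean = np.zeros(0)
        cov_sd = np.ones(0)
        Zs = np.zeros((len(obs), 0))

    A_sp = projection_matrix(mesh, locs)
    n_obs = len(obs)
    rows, cols, vals = [], [], []
    # intercept + fixed effects
    for i in range(n_obs):
        rows.append(i); cols.append(0); vals.append(1.0)
    for j in range(layout.n_fixed):
        for i in range(n_obs):
            rows.append(i); cols.append(1 + j); vals.append(Zs[i, j])
    # space-time block: barycentric row shifted into the time slice
    st0 = layout.spacetime.start
    cid_index = {c: k for k, c in enumerate(cluster_ids)}
    for i in range(n_obs):
        t_ar, t_seas = _time_axes(config, obs.at[i, "year"], obs.at[i, "season"])
        r0, r1 = A_sp.indptr[i], A_sp.indptr[i + 1]
        for jj, vv in zip(A_sp.indices[r0:r1], A_sp.data[r0:r1]):
            rows.append(i); cols.append(st0 + t_ar * n_v + jj); vals.append(vv)
        if config.model == 2:
            rows.append(i); cols.append(layout.seasonal.start + t_seas); vals.append(1.0)
        if cluster_ids:
            rows.append(i)
            cols.append(layout.cluster.start + cid_index[obs.at[i, "cluster_id"]])
            vals.append(1.0)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_obs, layout.total_dim))

    seasonal = prec.seasonal_structure(n_seas_axis, 4) if config.model == 2 else None

    # hyperparameter vector and data-independent initial values
    extent = max(np.ptp(mesh.vertices[:, 0]), np.ptp(mesh.vertices[:, 1]))
    range0 = config.init_spatial_range or extent / 4.0
    tau0, kappa0 = prec.matern_parameters(range0, config.init_spatial_sd)
    p_b = basis.B_tau.shape[1] - 1
    psi_names = (
        [f"log_tau_{k}" for k in range(1 + p_b)]
        + [f"log_kappa_{k}" for k in range(1 + p_b)]
        + ["z_pacf1", "z_pacf2"]
    )
    psi_init = [np.log(tau0)] + [0.0] * p_b + [np.log(kappa0)] + [0.0] * p_b
    psi_init += [1.1, 0.2]  # pacf approx (0.5, 0.1)
    if config.model == 2:
        psi_names.append("log_prec_seasonal")
        psi_init.append(3.0)
    if cluster_ids:
        psi_names.append("log_prec_cluster")
        psi_init.append(2.0)

    return _Structure(
        config=config,
        mesh=mesh,
        fem=fem,
        basis=basis,
        layout=layout,
        A=A,
        y=obs["n_wasted"].to_numpy(dtype=float),
        n=obs["n_examined"].to_numpy(dtype=float),
        seasonal=seasonal,
        cov_mean=cov_mean,
        cov_sd=cov_sd,
        cluster_ids=cluster_ids,
        psi_names=psi_names,
        psi_init=np.array(psi_init),
        n_seasonal_axis=n_seas_axis,
    )


def _unpack_psi(structure: _Structure, psi: np.ndarray) -> dict:
    p_b = structure.basis.B_tau.shape[1] - 1
    i = 0
    theta_tau = psi[i : i + 1 + p_b]; i += 1 + p_b
    theta_kappa = psi[i : i + 1 + p_b]; i += 1 + p_b
    pacf1 = float(np.tanh(psi[i])); pacf2 = float(np.tanh(psi[i + 1])); i += 2
    out = {"theta_tau": theta_tau, "theta_kappa": theta_kappa,
           "pacf": (pacf1, pacf2)}
    if structure.config.model == 2:
        out["log_prec_seasonal"] = float(psi[i]); i += 1
    if structure.cluster_ids:
        out["log_prec_cluster"] = float(psi[i]); i += 1
    return out


def _prior_precision(structure: _Structure, psi: np.ndarray):
    """(Q(psi), logdet Q(psi)) using the Kronecker determinant identity."""
    cfg = structure.config
    lay = structure.layout
    h = _unpack_psi(structure, psi)
    tau, kappa = prec.evaluate_parameter_fields(
        structure.basis, h["theta_tau"], h["theta_kappa"]
    )
    Qs = prec.spatial_precision(structure.fem, tau, kappa)
    Qt = prec.ar2_precision(lay.n_time, prec.AR2Params(*h["pacf"])) \
        if lay.n_time >= 3 else sp.identity(lay.n_time, format="csr")
    Qst = prec.spacetime_precision(Qs, Qt)

    lu_s = splu(Qs.tocsc())
    logdet_s = float(np.sum(np.log(np.abs(lu_s.U.diagonal()))))
    logdet_t = float(np.linalg.slogdet(Qt.toarray())[1])
    logdet = lay.n_time * logdet_s + lay.n_spatial * logdet_t
    logdet += (1 + lay.n_fixed) * np.log(cfg.fixed_prior_prec)

    Q = prec.assemble_joint_precision(
        lay,
        Qst,
        seasonal=structure.seasonal,
        seasonal_log_prec=h.get("log_prec_seasonal", 0.0),
        cluster_log_prec=h.get("log_prec_cluster", 0.0),
        fixed_prior_prec=cfg.fixed_prior_prec,
        seasonal_ridge=cfg.seasonal_ridge,
    )
    if lay.n_seasonal:
        Sb = (
            np.exp(h["log_prec_seasonal"]) * structure.seasonal.S
            + cfg.seasonal_ridge * sp.identity(lay.n_seasonal)
        ).toarray()
        logdet += float(np.linalg.slogdet(Sb)[1])
    if lay.n_cluster:
        logdet += lay.n_cluster * h["log_prec_cluster"]
    return Q, logdet


def _loglik(structure: _Structure, eta):
    if structure.config.likelihood == "binomial":
        return binomial_loglik(eta, structure.y, structure.n)
    return _gaussian_loglik(eta, structure.y, structure.config.gaussian_noise_sd)


def _inner_newton(structure, Q, theta0=None, max_iter=50, gtol=1e-6):
    """Mode of the latent field at fixed psi; returns (mode, lu(H), W, ok)."""
    A = structure.A
    theta = np.zeros(Q.shape[0]) if theta0 is None else theta0.copy()
    Qc = Q.tocsc()

    def objective(th):
        return _loglik(structure, A @ th)[0] - 0.5 * float(th @ (Q @ th))

    obj = objective(theta)
    lu = None
    w = None
    ok = False
    for _ in range(max_iter):
        eta = A @ theta
        _, g, w = _loglik(structure, eta)
        grad = A.T @ g - Q @ theta
        if np.max(np.abs(grad)) < gtol:
            ok = True
            break
        H = (Qc + (A.T @ sp.diags(w) @ A).tocsc()).tocsc()
        lu = splu(H)
        step = lu.solve(grad)
        # step halving keeps the objective non-decreasing
        s = 1.0
        for _ in range(30):
            cand = theta + s * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                theta, obj = cand, cand_obj
                break
            s *= 0.5
        else:
            break
    eta = A @ theta
    _, _, w = _loglik(structure, eta)
    H = (Qc + (A.T @ sp.diags(w) @ A).tocsc()).tocsc()
    lu = splu(H)
    return theta, lu, w, ok


def _log_marginal(structure, psi, theta_warm=None):
    """Laplace approximation to log p(y, psi) (up to a constant)."""
    try:
        Q, logdet_Q = _prior_precision(structure, psi)
    except (ValueError, RuntimeError):
        return -np.inf, None
    theta, lu, w, ok = _inner_newton(structure, Q, theta_warm)
    if not ok and theta_warm is not None:
        theta, lu, w, ok = _inner_newton(structure, Q)
    ll = _loglik(structure, structure.A @ theta)[0]
    logdet_H = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    lp_psi = -0.5 * float(
        np.sum(((psi - structure.psi_init) / structure.config.hyper_prior_sd) ** 2)
    )
    val = ll - 0.5 * float(theta @ (Q @ theta)) + 0.5 * logdet_Q - 0.5 * logdet_H + lp_psi
    if not np.isfinite(val):
        return -np.inf, None
    return val, theta


@dataclass
class PosteriorResult:
    """Gaussian (Laplace) approximation at the hyperparameter mode."""

    structure: _Structure = field(repr=False)
    mode: np.ndarray = field(repr=False)
    psi_hat: np.ndarray
    psi_names: list
    log_posterior: float
    converged: bool
    n_outer_evals: int
    fixed_summary: pd.DataFrame = None
    seed: int | None = None
    _Q: sp.csr_matrix = field(default=None, repr=False)
    _lu: object = field(default=None, repr=False)
    _W: np.ndarray = field(default=None, repr=False)

    @property
    def layout(self) -> prec.LatentLayout:
        return self.structure.layout

    def marginal_sd(self, indices) -> np.ndarray:
        """Marginal posterior SDs of latent components by index."""
        indices = np.atleast_1d(indices)
        out = np.empty(len(indices))
        for k, j in enumerate(indices):
            e = np.zeros(self.layout.total_dim)
            e[j] = 1.0
            out[k] = np.sqrt(max(self._lu.solve(e)[j], 0.0))
        return out

    def linear_predictor(self, A_pred: sp.csr_matrix, with_sd: bool = True):
        mean = A_pred @ self.mode
        if not with_sd:
            return mean, None
        V = self._lu.solve(np.asarray(A_pred.T.todense()))
        var = np.einsum("ij,ji->i", A_pred.toarray(), V)
        return mean, np.sqrt(np.maximum(var, 0.0))

    def hyperparameters(self) -> dict:
        h = _unpack_psi(self.structure, self.psi_hat)
        tau, kappa = prec.evaluate_parameter_fields(
            self.structure.basis, h["theta_tau"], h["theta_kappa"]
        )
        out = dict(zip(self.psi_names, self.psi_hat))
        out["pacf"] = h["pacf"]
        out["spatial_range_km_median"] = float(np.median(np.sqrt(8.0) / kappa))
        out["spatial_sd_median"] = float(
            np.median(1.0 / np.sqrt(4.0 * np.pi) / (kappa * tau))
        )
        return out


def _fixed_effect_summary(result: PosteriorResult) -> pd.DataFrame:
    lay = result.layout
    cfg = result.structure.config
    idx = [0] + list(range(1, 1 + lay.n_fixed))
    names = ["intercept"] + list(cfg.covariates)
    sds = result.marginal_sd(idx)
    rows = []
    for name, j, sd in zip(names, idx, sds):
        m = result.mode[j]
        rows.append(
            {
                "name": name,
                "mean": m,
                "sd": sd,
                "q02_5": m - 1.959963984540054 * sd,
                "q97_5": m + 1.959963984540054 * sd,
                "odds": float(np.exp(m)),
            }
        )
    return pd.DataFrame(rows)


def laplace_fit(
    observations: pd.DataFrame,
    model_config: ModelConfig,
    optimizer_config: dict | None = None,
    seed: int = 0,
) -> PosteriorResult:
    """Fit the model: empirical-Bayes psi at the Laplace-marginal mode,
    then the Gaussian approximation to the latent field at that mode.

    ``optimizer_config`` keys: maxiter (Nelder-Mead evaluations, default
    150), restarts (default 1 extra jittered start), xatol/fatol.
    """
    oc = {"maxiter": 150, "restarts": 1, "xatol": 1e-3, "fatol": 1e-3}
    oc.update(optimizer_config or {})
    structure = build_structure(observations, model_config)
    rng = np.random.default_rng(seed)

    warm = {"theta": None}

    def neg(psi):
        val, theta = _log_marginal(structure, psi, warm["theta"])
        if theta is not None:
            warm["theta"] = theta
        return -val

    starts = [structure.psi_init.copy()]
    for _ in range(int(oc["restarts"])):
        starts.append(structure.psi_init + 0.5 * rng.standard_normal(
            structure.psi_init.shape))
    best = None
    n_evals = 0
    for x0 in starts:
        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": oc["maxiter"],
                "xatol": oc["xatol"],
                "fatol": oc["fatol"],
            },
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    psi_hat = best.x

    Q, _ = _prior_precision(structure, psi_hat)
    mode, lu, w, ok = _inner_newton(structure, Q, warm["theta"])
    result = PosteriorResult(
        structure=structure,
        mode=mode,
        psi_hat=psi_hat,
        psi_names=structure.psi_names,
        log_posterior=-best.fun,
        converged=bool(ok),
        n_outer_evals=n_evals,
        seed=seed,
        _Q=Q,
        _lu=lu,
        _W=w,
    )
    result.fixed_summary = _fixed_effect_summary(result)
    return result


@dataclass
class PrevalenceGrid:
    """Posterior prevalence surfaces per requested (year, season)."""

    grids: dict  # (year, season) -> Grid of posterior mean prevalence
    sd_grids: dict  # (year, season) -> Grid of posterior SD (delta method)
    n_masked: int  # pixels outside the mesh (NaN in the surfaces)


def predict_prevalence(
    fit: PosteriorResult,
    prediction_grid,
    covariate_rasters: dict,
    which: list,
    monte_carlo: int = 0,
    seed: int = 0,
    with_sd: bool = True,
) -> PrevalenceGrid:
    """Posterior mean (and SD) prevalence on a pixel grid.

    Default: inverse-logit of the posterior-mean linear predictor, with the
    pixel SD mapped through the delta method p(1-p) sd(eta).  With
    ``monte_carlo`` > 0 the mean averages inverse-logit over Gaussian draws
    of eta instead.  Cluster effects are population-level zero at
    prediction.  Pixels outside the mesh are masked (NaN), not an error.
    """
    cfg = fit.structure.config
    lay = fit.layout
    px, py = prediction_grid.centers()
    shape = prediction_grid.values.shape
    n_pix = px.size
    rng = np.random.default_rng(seed)

    Zs = np.zeros((n_pix, lay.n_fixed))
    for j, name in enumerate(cfg.covariates):
        vals = covariate_rasters[name].interp(px, py)
        Zs[:, j] = (vals - fit.structure.cov_mean[j]) / fit.structure.cov_sd[j]

    A_sp, outside = projection_matrix(
        fit.structure.mesh, np.column_stack([px, py]), on_outside="mask"
    )
    inside = np.ones(n_pix, dtype=bool)
    inside[outside] = False

    grids, sd_grids = {}, {}
    for year, season in which:
        t_ar, t_seas = _time_axes(cfg, year, season)
        rows, cols, vals = [], [], []
        for i in range(n_pix):
            if not inside[i]:
                continue
            rows.append(i); cols.append(0); vals.append(1.0)
            for j in range(lay.n_fixed):
                rows.append(i); cols.append(1 + j); vals.append(Zs[i, j])
            r0, r1 = A_sp.indptr[i], A_sp.indptr[i + 1]
            st0 = lay.spacetime.start
            for jj, vv in zip(A_sp.indices[r0:r1], A_sp.data[r0:r1]):
                rows.append(i); cols.append(st0 + t_ar * lay.n_spatial + jj)
                vals.append(vv)
            if cfg.model == 2:
                rows.append(i); cols.append(lay.seasonal.start + t_seas)
                vals.append(1.0)
        A_pred = sp.csr_matrix((vals, (rows, cols)), shape=(n_pix, lay.total_dim))
        eta, eta_sd = fit.linear_predictor(A_pred, with_sd=with_sd or monte_carlo > 0)
        if monte_carlo > 0:
            draws = eta[None, :] + eta_sd[None, :] * rng.standard_normal(
                (monte_carlo, n_pix)
            )
            p_mean = expit(draws).mean(axis=0)
        else:
            p_mean = expit(eta)
        p_mean[~inside] = np.nan
        grids[(year, season)] = prediction_grid.with_values(p_mean.reshape(shape))
        if with_sd:
            p_sd = expit(eta) * (1 - expit(eta)) * eta_sd
            p_sd[~inside] = np.nan
            sd_grids[(year, season)] = prediction_grid.with_values(
                p_sd.reshape(shape)
            )
    return PrevalenceGrid(grids=grids, sd_grids=sd_grids, n_masked=len(outside))


def predict_prevalence_at_points(
    fit: PosteriorResult,
    observations: pd.DataFrame,
    covariate_rasters: dict | None = None,
) -> np.ndarray:
    """Posterior-mean prevalence at cluster records (e.g. a hold-out set).

    Covariate values come from the observation columns when present,
    falling back to interpolation from ``covariate_rasters``.  Cluster
    effects are set to their population-level zero, so this is an
    out-of-cluster prediction.
    """
    cfg = fit.structure.config
    lay = fit.layout
    obs = observations.reset_index(drop=True)
    locs = obs[["x_km", "y_km"]].to_numpy(dtype=float)
    n_obs = len(obs)

    Zs = np.zeros((n_obs, lay.n_fixed))
    for j, name in enumerate(cfg.covariates):
        if name in obs.columns:
            vals = obs[name].to_numpy(dtype=float)
        elif covariate_rasters and name in covariate_rasters:
            vals = covariate_rasters[name].interp(locs[:, 0], locs[:, 1])
        else:
            raise KeyError(f"no covariate values available for {name!r}")
        Zs[:, j] = (vals - fit.structure.cov_mean[j]) / fit.structure.cov_sd[j]

    A_sp = projection_matrix(fit.structure.mesh, locs)
    rows, cols, vals = [], [], []
    st0 = lay.spacetime.start
    for i in range(n_obs):
        t_ar, t_seas = _time_axes(cfg, obs.at[i, "year"], obs.at[i, "season"])
        rows.append(i); cols.append(0); vals.append(1.0)
        for j in range(lay.n_fixed):
            rows.append(i); cols.append(1 + j); vals.append(Zs[i, j])
        r0, r1 = A_sp.indptr[i], A_sp.indptr[i + 1]
        for jj, vv in zip(A_sp.indices[r0:r1], A_sp.data[r0:r1]):
            rows.append(i); cols.append(st0 + t_ar * lay.n_spatial + jj)
            vals.append(vv)
        if cfg.model == 2:
            rows.append(i); cols.append(lay.seasonal.start + t_seas); vals.append(1.0)
    A_pred = sp.csr_matrix((vals, (rows, cols)), shape=(n_obs, lay.total_dim))
    eta, _ = fit.linear_predictor(A_pred, with_sd=False)
    return expit(eta)


def seasonal_effect_estimates(fit_model2: PosteriorResult) -> pd.DataFrame:
    """Per-season posterior mean log-odds effects with 95% intervals.

    Averages the shared seasonal component over years for each of the four
    seasons and centres the four values to sum exactly to zero (the
    identifiability constraint against the intercept).
    """
    if fit_model2.structure.config.model != 2:
        raise ValueError("seasonal effects require a model-2 fit")
    lay = fit_model2.layout
    n_axis = lay.n_seasonal
    n_years = n_axis // 4
    # contrast: average of each season over years, then centre
    P = np.zeros((4, n_axis))
    for s in range(4):
        P[s, [4 * yi + s for yi in range(n_years)]] = 1.0 / n_years
    L = P - P.mean(axis=0, keepdims=True)

    x_seas = fit_model2.mode[lay.seasonal]
    est = L @ x_seas
    est -= est.mean()  # exact sum-to-zero

    # covariance of the contrasts via solves on the full Hessian
    cov = np.zeros((4, 4))
    s0 = lay.seasonal.start
    for s in range(4):
        e = np.zeros(lay.total_dim)
        e[s0 : s0 + n_axis] = L[s]
        v = fit_model2._lu.solve(e)
        cov[s] = L @ v[s0 : s0 + n_axis]
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = 1.959963984540054
    return pd.DataFrame(
        {
            "season": list(SEASONS),
            "mean_log_odds": est,
            "sd": sd,
            "q02_5": est - z * sd,
            "q97_5": est + z * sd,
        }
    )


def mcmc_oracle(
    observations: pd.DataFrame,
    model_config: ModelConfig,
    fixed_psi: np.ndarray,
    n_iter: int = 5000,
    seed: int = 0,
    burn_in: int | None = None,
    step_scale: float = 0.3,
):
    """Preconditioned MALA samples of the latent field at fixed psi.

    Dense, test-scale only (latent dimension capped at 2000).  The
    preconditioner is the prior precision plus the binomial curvature bound
    A' diag(n/4) A — fixed in advance, independent of any Laplace fit.
    Returns a dict with posterior means, SDs, effective sample sizes and
    Monte-Carlo standard errors.
    """
    structure = build_structure(observations, model_config)
    d = structure.layout.total_dim
    if d > 2000:
        raise ValueError(f"latent dimension {d} exceeds the oracle guard (2000)")
    rng = np.random.default_rng(seed)
    Q, _ = _prior_precision(structure, np.asarray(fixed_psi, dtype=float))
    Qd = Q.toarray()
    A = structure.A

    if model_config.likelihood == "binomial":
        bound = structure.n / 4.0
    else:
        bound = np.full(len(structure.n), 1.0 / model_config.gaussian_noise_sd**2)
    M = Qd + (A.T @ sp.diags(bound) @ A).toarray()
    from scipy.linalg import cho_factor, cho_solve, cholesky

    cf = cho_factor(M, lower=True)
    L = cholesky(M, lower=True)

    def logpost_grad(th):
        eta = A @ th
        ll, g, _ = _loglik(structure, eta)
        return ll - 0.5 * float(th @ (Qd @ th)), A.T @ g - Qd @ th

    burn = n_iter // 4 if burn_in is None else burn_in
    eps = step_scale
    theta = np.zeros(d)
    lp, gr = logpost_grad(theta)
    samples = np.empty((n_iter, d))
    n_acc = 0
    for it in range(burn + n_iter):
        drift = 0.5 * eps**2 * cho_solve(cf, gr)
        noise = eps * np.linalg.solve(L.T, rng.standard_normal(d))
        prop = theta + drift + noise
        lp_p, gr_p = logpost_grad(prop)
        # proposal density ratio under the M-preconditioned kernel
        fwd = prop - theta - 0.5 * eps**2 * cho_solve(cf, gr)
        bwd = theta - prop - 0.5 * eps**2 * cho_solve(cf, gr_p)
        log_q_fwd = -0.5 / eps**2 * float(fwd @ (M @ fwd))
        log_q_bwd = -0.5 / eps**2 * float(bwd @ (M @ bwd))
        log_alpha = lp_p - lp + log_q_bwd - log_q_fwd
        if np.log(rng.uniform()) < log_alpha:
            theta, lp, gr = prop, lp_p, gr_p
            n_acc += 1
        if it < burn:
            # stochastic-approximation tuning toward 0.57 acceptance
            rate = min(np.exp(log_alpha), 1.0)
            eps *= np.exp(0.5 * (rate - 0.574) / np.sqrt(it + 1))
        else:
            samples[it - burn] = theta

    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    ess = np.array([_ess(samples[:, j]) for j in range(d)])
    se = sd / np.sqrt(np.maximum(ess, 1.0))
    return {
        "mean": mean,
        "sd": sd,
        "ess": ess,
        "se": se,
        "acceptance": n_acc / (burn + n_iter),
        "layout": structure.layout,
        "n_iter": n_iter,
    }


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    n = len(x)
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n] / (n * var)
    s = 1.0
    for k in range(1, n):
        if acf[k] < 0:
            break
        s += 2.0 * acf[k]
    return float(n / max(s, 1.0))
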