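"""Structured precision matrices for the latent Gaussian model.

Assembles every prior block of the latent field: the (possibly
non-stationary) spatial SPDE precision, the stationary AR(2) temporal
precision, their separable Kronecker space-time product, the period-m
seasonal precision, and the joint precision over
(intercept, fixed effects, space-time weights, seasonal effects, cluster
effects).

Conventions
-----------
* The temporal AR(2) block is scaled to unit marginal variance; the overall
  field variance is carried by the spatial tau(u) field.  This avoids the
  usual confounding between temporal and spatial scales in separable models.
* Non-stationarity enters through log-linear basis expansions
  log tau(u) = B_tau theta_tau, log kappa(u) = B_kappa theta_kappa, with an
  all-ones first basis column, so intercept-only coefficients reproduce the
  stationary Matern (nu=1) model with range sqrt(8)/kappa and marginal
  variance 1/(4 pi kappa^2 tau^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import toeplitz


@dataclass
class ParameterFieldBasis:
    """Basis matrices for the log tau / log kappa fields at mesh nodes."""

    B_tau: np.ndarray  # (n_v, 1 + p_b), first column all ones
    B_kappa: np.ndarray

    def __post_init__(self):
        for name, B in (("B_tau", self.B_tau), ("B_kappa", self.B_kappa)):
            B = np.asarray(B, dtype=float)
            if not np.all(np.isfinite(B)):
                raise ValueError(f"{name} has non-finite entries")
            if not np.allclose(B[:, 0], 1.0):
                raise ValueError(f"first column of {name} must be all ones")


def intercept_basis(n_v: int) -> ParameterFieldBasis:
    """Stationary model: intercept-only basis for both parameter fields."""
    B = np.ones((n_v, 1))
    return ParameterFieldBasis(B_tau=B, B_kappa=B.copy())


def linear_basis(vertices: np.ndarray) -> ParameterFieldBasis:
    """Intercept + centred/scaled linear-in-x and linear-in-y basis."""
    v = np.asarray(vertices, dtype=float)
    xy = (v - v.mean(axis=0)) / np.maximum(v.std(axis=0), 1e-12)
    B = np.column_stack([np.ones(len(v)), xy])
    return ParameterFieldBasis(B_tau=B, B_kappa=B.copy())


def evaluate_parameter_fields(basis, theta_tau, theta_kappa):
    """tau_i = exp(B_tau theta_tau), kappa_i = exp(B_kappa theta_kappa)."""
    theta_tau = np.asarray(theta_tau, dtype=float)
    theta_kappa = np.asarray(theta_kappa, dtype=float)
    if not (np.all(np.isfinite(theta_tau)) and np.all(np.isfinite(theta_kappa))):
        raise ValueError("non-finite basis coefficients")
    tau = np.exp(basis.B_tau @ theta_tau)
    kappa = np.exp(basis.B_kappa @ theta_kappa)
    return tau, kappa


def matern_parameters(spatial_range: float, marginal_sd: float):
    """Map (range, sd) of the Matern nu=1 field to stationary (tau, kappa).

    range = sqrt(8 nu)/kappa with nu = 1; sd^2 = 1/(4 pi kappa^2 tau^2).
    """
    if spatial_range <= 0 or marginal_sd <= 0:
        raise ValueError("range and sd must be positive")
    kappa = np.sqrt(8.0) / spatial_range
    tau = 1.0 / (marginal_sd * kappa * np.sqrt(4.0 * np.pi))
    return tau, kappa


def spatial_precision(fem, tau_i, kappa_i) -> sp.csr_matrix:
    """Non-stationary alpha=2 SPDE precision
    Q = T (K2 C K2 + K2 G1 + G1 K2 + G2) T with T = diag(tau), K2 = diag(kappa^2).
    """
    tau_i = np.asarray(tau_i, dtype=float)
    kappa_i = np.asarray(kappa_i, dtype=float)
    if np.any(tau_i <= 0) or np.any(kappa_i <= 0):
        raise ValueError("tau and kappa fields must be strictly positive")
    c = fem.C.diagonal()
    k2 = kappa_i**2
    K2 = sp.diags(k2)
    M = sp.diags(k2 * c * k2) + K2 @ fem.G1 + fem.G1 @ K2 + fem.G2
    T = sp.diags(tau_i)
    Q = (T @ M @ T).tocsr()
    return (0.5 * (Q + Q.T)).tocsr()


@dataclass
class AR2Params:
    """Stationary AR(2) in partial-autocorrelation parameterization.

    pacf1, pacf2 in (-1, 1) guarantee stationarity; the AR coefficients are
    a1 = pacf1 (1 - pacf2), a2 = pacf2 (Durbin-Levinson).
    """

    pacf1: float
    pacf2: float = 0.0

    def __post_init__(self):
        if not (abs(self.pacf1) < 1 and abs(self.pacf2) < 1):
            raise ValueError("partial autocorrelations must lie in (-1, 1)")

    @property
    def ar_coefficients(self):
        return self.pacf1 * (1.0 - self.pacf2), self.pacf2

    def autocorrelation(self, n_lags: int) -> np.ndarray:
        """Autocorrelation function rho_0..rho_{n_lags-1} via Yule-Walker."""
        a1, a2 = self.ar_coefficients
        rho = np.empty(max(n_lags, 2))
        rho[0] = 1.0
        rho[1] = a1 / (1.0 - a2)
        for k in range(2, len(rho)):
            rho[k] = a1 * rho[k - 1] + a2 * rho[k - 2]
        return rho[:n_lags]


def ar2_precision(n_t: int, params: AR2Params) -> sp.csr_matrix:
    """Precision of a stationary unit-marginal-variance AR(2) of length n_t.

    Built as the inverse of the Toeplitz autocorrelation matrix; the exact
    inverse has bandwidth 2, so entries beyond the band (numerical noise)
    are dropped.
    """
    if n_t < 3:
        raise ValueError("n_t must be at least 3")
    rho = params.autocorrelation(n_t)
    Q = np.linalg.inv(toeplitz(rho))
    Q = 0.5 * (Q + Q.T)
    mask = np.abs(np.subtract.outer(np.arange(n_t), np.arange(n_t))) <= 2
    return sp.csr_matrix(Q * mask)


@dataclass
class SeasonalModel:
    """Period-m seasonal GMRF: m-term moving sums are iid N(0, 1/tau).

    The structure matrix S = D' D (D the (n-m+1) x n moving-sum matrix) has
    rank n-m+1; its null space is exactly the period-m patterns with zero
    cycle sum, i.e. the pure seasonal signals the prior leaves free.
    """

    n: int
    m: int
    S: sp.csr_matrix = field(repr=False)
    D: sp.csr_matrix = field(repr=False)

    def log_density(self, x: np.ndarray, tau: float) -> float:
        """Unnormalized log pi(x | tau) = ((n-m+1)/2) log tau - (tau/2) x'Sx."""
        x = np.asarray(x, dtype=float)
        return 0.5 * (self.n - self.m + 1) * np.log(tau) - 0.5 * tau * float(
            x @ (self.S @ x)
        )


def seasonal_structure(n: int, m: int = 4) -> SeasonalModel:
    """Build the seasonal structure matrix from m-term moving sums."""
    if not n > m:
        raise ValueError("need n > m")
    if m < 2:
        raise ValueError("need m >= 2")
    n_inc = n - m + 1
    rows = np.repeat(np.arange(n_inc), m)
    cols = (np.arange(n_inc)[:, None] + np.arange(m)[None, :]).ravel()
    D = sp.csr_matrix((np.ones(n_inc * m), (rows, cols)), shape=(n_inc, n))
    S = (D.T @ D).tocsr()
    return SeasonalModel(n=n, m=m, S=S, D=D)


def spacetime_precision(Q_s, Q_t, max_dim: int = 500_000) -> sp.csr_matrix:
    """Separable space-time precision Q_t (x) Q_s (Kronecker product).

    Ordering: the joint weight vector stacks the spatial field time-slice by
    time-slice, w[(t * n_v):((t+1) * n_v)] = field at time t.
    """
    n = Q_s.shape[0] * Q_t.shape[0]
    if n > max_dim:
        raise ValueError(f"space-time dimension {n} exceeds cap {max_dim}")
    return sp.kron(Q_t, Q_s, format="csr")


@dataclass
class LatentLayout:
    """Index bookkeeping for the joint latent vector
    (intercept, fixed effects, space-time weights, seasonal, cluster)."""

    n_fixed: int  # covariate effects, excluding intercept
    n_spatial: int  # n_v
    n_time: int  # n_t (AR axis length)
    n_seasonal: int  # 0 for model 1
    n_cluster: int

    @property
    def intercept(self) -> slice:
        return slice(0, 1)

    @property
    def fixed(self) -> slice:
        return slice(1, 1 + self.n_fixed)

    @property
    def spacetime(self) -> slice:
        a = 1 + self.n_fixed
        return slice(a, a + self.n_spatial * self.n_time)

    @property
    def seasonal(self) -> slice:
        a = 1 + self.n_fixed + self.n_spatial * self.n_time
        return slice(a, a + self.n_seasonal)

    @property
    def cluster(self) -> slice:
        a = 1 + self.n_fixed + self.n_spatial * self.n_time + self.n_seasonal
        return slice(a, a + self.n_cluster)

    @property
    def total_dim(self) -> int:
        return (
            1
            + self.n_fixed
            + self.n_spatial * self.n_time
            + self.n_seasonal
            + self.n_cluster
        )


def assemble_joint_precision(
    layout: LatentLayout,
    Q_st,
    seasonal: SeasonalModel | None = None,
    seasonal_log_prec: float = 0.0,
    cluster_log_prec: float = 0.0,
    fixed_prior_prec: float = 1e-4,
    seasonal_ridge: float = 1e-4,
) -> sp.csr_matrix:
    """Block-diagonal joint prior precision Q(psi) over the latent layout.

    The seasonal block is tau_seas * S plus a weak ridge: S is rank
    deficient by construction (the pure seasonal patterns carry no penalty),
    and the ridge is the proper weak Gaussian prior that makes the joint
    precision strictly positive definite.
    """
    if Q_st.shape[0] != layout.n_spatial * layout.n_time:
        raise ValueError("space-time block does not match layout")
    blocks = [sp.identity(1 + layout.n_fixed, format="csr") * fixed_prior_prec, Q_st]
    if layout.n_seasonal:
        if seasonal is None or seasonal.n != layout.n_seasonal:
            raise ValueError("seasonal model does not match layout")
        blocks.append(
            np.exp(seasonal_log_prec) * seasonal.S
            + seasonal_ridge * sp.identity(layout.n_seasonal)
        )
    if layout.n_cluster:
        blocks.append(
            np.exp(cluster_log_prec) * sp.identity(layout.n_cluster, format="csr")
        )
    Q = sp.block_diag(blocks, format="csr")
    if Q.shape[0] != layout.total_dim:
        raise ValueError("assembled precision does not match layout dimension")
    return Q


def matern_nu1_correlation(r: np.ndarray, kappa: float) -> np.ndarray:
    """Matern nu=1 correlation (kappa r) K_1(kappa r), 1 at r = 0."""
    from scipy.special import kv

    r = np.asarray(r, dtype=float)
    out = np.ones_like(r)
    pos = r > 0
    x = kappa * r[pos]
    out[pos] = x * kv(1, x)
    return out
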