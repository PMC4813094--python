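"""Fully synthetic study generator with the structure the analysis assumes.

Emulates a bi-annual-seasons nutrition survey over a three-zone planar
region: smooth environmental covariate surfaces, survey clusters at random
locations, a latent spatial Matern field drawn from the same SPDE precision
used in inference, AR(2) year-season dynamics, a period-4 seasonal signal,
iid cluster effects, and binomial sampling of wasted counts with a logit
link.  Every generator is a pure function of its arguments and seed.

Default conditions: 1066 clusters over 4 years x 4 seasons, overall
prevalence near 21%, cluster sizes uniform on 30-120 children.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from shapely.geometry import box

from .grids import Grid
from .meshfem import build_mesh, fem_matrices, projection_matrix
from .precision import AR2Params, matern_parameters, spatial_precision

SEASONS = ("Jilaal", "Gu", "Hagaa", "Deyr")
COVARIATE_NAMES = ("rainfall", "evi", "temperature", "dist_water", "urban")


@dataclass
class StudyRegion:
    """Planar rectangular study region split into three named zones."""

    bbox: tuple  # (x_min, x_max, y_min, y_max), km
    zones: dict  # name -> shapely polygon; pairwise-disjoint interiors
    resolution: float  # pixel size, km

    @property
    def width(self) -> float:
        return self.bbox[1] - self.bbox[0]

    @property
    def height(self) -> float:
        return self.bbox[3] - self.bbox[2]

    @property
    def area(self) -> float:
        return self.width * self.height

    def grid_shape(self):
        nx = int(round(self.width / self.resolution))
        ny = int(round(self.height / self.resolution))
        return max(ny, 1), max(nx, 1)

    def empty_grid(self) -> Grid:
        ny, nx = self.grid_shape()
        return Grid(self.bbox[0], self.bbox[2], self.resolution, np.zeros((ny, nx)))


@dataclass
class TrueParameters:
    """Generator-side truth for the linear predictor on the log-odds scale.

    Defaults target the observed survey magnitudes: intercept at
    logit(0.21), covariate effects of the sign pattern reported for the
    real surfaces (negative rainfall and vegetation, positive temperature,
    null water-distance and urbanization), a 100 km / 0.35 SD spatial
    field, persistent AR(2) year-season dynamics, a centred seasonal cycle
    that raises the dry seasons, and mild cluster-level overdispersion.
    """

    beta0: float = float(logit(0.21))
    beta: dict = field(
        default_factory=lambda: {
            "rainfall": -0.20,
            "evi": -0.24,
            "temperature": 0.19,
            "dist_water": 0.0,
            "urban": 0.0,
        }
    )
    spatial_range: float = 100.0  # km
    spatial_sd: float = 0.35  # log-odds scale
    ar_pacf: tuple = (0.6, 0.1)
    seasonal_offsets: tuple = (0.035, -0.035, 0.025, -0.025)  # Jilaal,Gu,Hagaa,Deyr
    cluster_sd: float = 0.30

    def __post_init__(self):
        if any(abs(r) >= 1 for r in self.ar_pacf):
            raise ValueError("AR partial autocorrelations must lie in (-1, 1)")
        if abs(sum(self.seasonal_offsets)) > 1e-9:
            raise ValueError("seasonal offsets must sum to zero")
        if self.spatial_sd < 0 or self.cluster_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def make_study_region(
    width_km: float, height_km: float, resolution_km: float
) -> StudyRegion:
    """Rectangle [0, w] x [0, h] with three equal vertical-band zones."""
    if width_km <= 0 or height_km <= 0 or resolution_km <= 0:
        raise ValueError("width, height and resolution must be positive")
    thirds = np.linspace(0.0, width_km, 4)
    names = ("West", "Central", "East")
    zones = {
        name: box(thirds[i], 0.0, thirds[i + 1], height_km)
        for i, name in enumerate(names)
    }
    return StudyRegion(
        bbox=(0.0, width_km, 0.0, height_km), zones=zones, resolution=resolution_km
    )


def sample_cluster_locations(
    region: StudyRegion, n_clusters: int, seed: int = 0
) -> np.ndarray:
    """Uniform random cluster locations strictly inside the region."""
    if n_clusters < 0:
        raise ValueError("n_clusters must be nonnegative")
    rng = np.random.default_rng(seed)
    x_min, x_max, y_min, y_max = region.bbox
    margin = 1e-6
    x = rng.uniform(x_min + margin, x_max - margin, n_clusters)
    y = rng.uniform(y_min + margin, y_max - margin, n_clusters)
    return np.column_stack([x, y])


def _smooth_field(shape, rng, sigma_pixels: float) -> np.ndarray:
    """Standardized low-frequency Gaussian random surface."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma_pixels, mode="wrap")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def simulate_covariate_surfaces(region: StudyRegion, seed: int = 0) -> dict:
    """Smooth named covariate rasters on the region's pixel grid.

    Rainfall spans the observed monthly range [2, 104] mm, EVI lies in
    [0, 1], temperature is in deg C, distance-to-water in km, and urban is
    a 0/1 indicator covering roughly a tenth of pixels.
    """
    rng = np.random.default_rng(seed)
    shape = region.grid_shape()
    sigma = max(min(shape) / 6.0, 1.0)
    g = region.empty_grid()

    z_rain = _smooth_field(shape, rng, sigma)
    rainfall = np.clip(53.0 + 25.0 * z_rain, 2.0, 104.0)
    evi = expit(0.9 * _smooth_field(shape, rng, sigma))
    temperature = 27.0 + 4.0 * _smooth_field(shape, rng, sigma)
    z_w = _smooth_field(shape, rng, sigma)
    dist_water = 30.0 * np.log1p(np.exp(z_w))
    z_u = _smooth_field(shape, rng, sigma)
    urban = (z_u >= np.quantile(z_u, 0.9)).astype(float)
    return {
        "rainfall": g.with_values(rainfall),
        "evi": g.with_values(evi),
        "temperature": g.with_values(temperature),
        "dist_water": g.with_values(dist_water),
        "urban": g.with_values(urban),
    }


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / (sd if sd > 0 else 1.0)


def time_index(year: int, season: str, first_year: int) -> int:
    """Single temporal axis: t = 4 (year - first_year) + season index."""
    return 4 * (year - first_year) + SEASONS.index(season)


def _sample_spacetime_field(
    region, true_params: TrueParameters, n_t: int, rng, mesh_edge_km: float
):
    """Draw one realization of the separable space-time field on a mesh.

    The spatial factor uses the same stationary SPDE precision the
    inference module assembles; the temporal factor is the stationary
    unit-variance AR(2).  Sampling uses the Kronecker identity
    vec(L_s^-T Z L_t^-1) ~ N(0, Q_t^-1 (x) Q_s^-1).
    """
    mesh = build_mesh(region, max_edge_km=mesh_edge_km, buffer_km=true_params.spatial_range)
    fem = fem_matrices(mesh)
    tau, kappa = matern_parameters(true_params.spatial_range, true_params.spatial_sd)
    Qs = spatial_precision(
        fem, np.full(mesh.n_vertices, tau), np.full(mesh.n_vertices, kappa)
    ).toarray()
    from .precision import ar2_precision

    if n_t >= 3:
        Qt = ar2_precision(n_t, AR2Params(*true_params.ar_pacf)).toarray()
    else:
        Qt = np.eye(n_t)
    Ls = cholesky(Qs, lower=True)
    Lt = cholesky(Qt, lower=True)
    Z = rng.standard_normal((mesh.n_vertices, n_t))
    W = solve_triangular(Ls.T, Z, lower=False)
    W = solve_triangular(Lt, W.T, lower=True, trans="T").T  # right-multiply Lt^-1
    return mesh, W  # (n_v, n_t)


def simulate_wasting_data(
    region: StudyRegion,
    locations: np.ndarray,
    covariates: dict,
    true_params: TrueParameters,
    years=(2007, 2008, 2009, 2010),
    n_per_cluster=(30, 120),
    seed: int = 0,
    all_times: bool = False,
    mesh_edge_km: float = 40.0,
) -> pd.DataFrame:
    """Binomial cluster records from the full generative model.

    Each cluster is observed at one uniformly drawn (year, season) unless
    ``all_times`` is set, in which case every cluster x year x season combo
    is generated.  The linear predictor stacks intercept, standardized
    covariate effects, the space-time field draw, seasonal offsets and iid
    cluster effects; wasted counts are Binomial(n_examined,
    inverse-logit(eta)).
    """
    unknown = set(true_params.beta) - set(covariates)
    if unknown:
        raise KeyError(f"beta names without covariate surfaces: {sorted(unknown)}")
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    rng = np.random.default_rng(seed)
    years = tuple(years)
    n_t = 4 * len(years)
    n_c = len(locations)

    cov_at = {
        name: grid.interp(locations[:, 0], locations[:, 1])
        for name, grid in covariates.items()
    }
    cov_std = {name: _standardize(v) for name, v in cov_at.items()}

    if true_params.spatial_sd > 0 and n_c > 0:
        mesh, W = _sample_spacetime_field(
            region, true_params, n_t, rng, mesh_edge_km
        )
        A = projection_matrix(mesh, locations)
        field_ct = A @ W  # marginal SD is carried by tau inside Q_s
    else:
        field_ct = np.zeros((n_c, n_t))

    cluster_eff = rng.normal(0.0, true_params.cluster_sd, n_c)

    if all_times:
        combos = [(c, y, s) for c in range(n_c) for y in years for s in SEASONS]
    else:
        yi = rng.integers(0, len(years), n_c)
        si = rng.integers(0, 4, n_c)
        combos = [(c, years[yi[c]], SEASONS[si[c]]) for c in range(n_c)]

    lo, hi = n_per_cluster
    if lo < 1:
        raise ValueError("n_per_cluster must be at least 1")
    rows = []
    for c, year, season in combos:
        t = time_index(year, season, years[0])
        eta = (
            true_params.beta0
            + sum(
                b * cov_std[name][c] for name, b in true_params.beta.items()
            )
            + field_ct[c, t]
            + true_params.seasonal_offsets[SEASONS.index(season)]
            + cluster_eff[c]
        )
        n_ex = int(rng.integers(lo, hi + 1))
        n_w = int(rng.binomial(n_ex, expit(eta)))
        row = {
            "cluster_id": f"c{c:04d}",
            "x_km": locations[c, 0],
            "y_km": locations[c, 1],
            "year": year,
            "season": season,
            "n_examined": n_ex,
            "n_wasted": n_w,
        }
        row.update({name: float(cov_at[name][c]) for name in covariates})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_population_grid(
    region: StudyRegion, total_under5: int, seed: int = 0
) -> Grid:
    """Smooth, clumped under-five population raster summing exactly to total.

    Weights are a softplus of a smooth random surface (population
    concentrates where the surface is high); integer counts come from
    largest-remainder allocation so the pixel sum equals ``total_under5``.
    """
    if total_under5 < 0:
        raise ValueError("total_under5 must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = region.grid_shape()
    g = region.empty_grid()
    if total_under5 == 0:
        return g
    z = _smooth_field(shape, rng, max(min(shape) / 6.0, 1.0))
    w = np.log1p(np.exp(3.0 * z)).ravel()
    quota = w / w.sum() * total_under5
    base = np.floor(quota).astype(int)
    short = total_under5 - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return g.with_values(base.reshape(shape).astype(float))
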