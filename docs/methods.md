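# Methods

## Observation model and latent structure

Cluster records are binomial: `y_i ~ Binomial(n_i, p_i)` with a logit
link. The choice of logit (rather than probit or cloglog) makes the fixed
effects interpretable as odds ratios, the scale on which wasting effect
sizes are conventionally reported. The latent field stacks, in order:
intercept, covariate effects, space-time SPDE weights, seasonal effects
(model 2 only), and iid cluster effects; the whole vector has a joint
Gaussian prior `N(0, Q(psi)^-1)` with block-diagonal precision.

The intercept and covariate effects get a weak Gaussian prior (precision
1e-4) rather than an improper flat prior so that the joint precision is
strictly positive definite and one sparse factorization covers every
block.

## Spatial field: SPDE / finite elements

The Matern nu = 1 field solves `(kappa^2 - Laplacian)(tau x) = W` on the
meshed domain; with piecewise-linear elements this yields the sparse
precision `Q = T (K^2 C K^2 + K^2 G1 + G1 K^2 + G2) T`, where `C` is the
lumped (diagonal) mass matrix, `G1` the stiffness matrix and
`G2 = G1 C^-1 G1`. Mass lumping keeps `Q` sparse; the accuracy cost shows
up only at mesh scale and is covered by the Matern-equivalence test
below. Stationary parameters map to interpretable quantities by
`range = sqrt(8)/kappa` and `sd^2 = 1/(4 pi kappa^2 tau^2)`.

Non-stationarity enters through `log tau(u) = B theta_tau`,
`log kappa(u) = B theta_kappa`. The default basis is intercept-only
(stationary); an intercept + linear x + linear y basis is available as
the smallest non-trivial extension. With the basis unspecified by the
problem, anything richer would be unidentifiable at survey sample sizes.

The mesh is a structured triangulation of the bounding box plus an outer
buffer (default 80 km, about one prior range) to keep the Neumann
boundary condition from inflating variance inside the domain. Grid
spacing is `max_edge/sqrt(2)` so that no edge, including cell diagonals,
exceeds the requested maximum. A structured mesh was chosen over
constrained Delaunay because it is deterministic, never degenerate, and
needs no meshing dependency; the buffer uses the same spacing — at the
problem sizes used here the extra vertices are cheap, and a uniform mesh
keeps the FEM error spatially homogeneous.

Verification: on a fine mesh (edge 0.33 on a 10 x 10 domain, range 2.5)
the dense inverse of `Q` reproduces the Matern nu = 1 correlation
`(kappa r) K_1(kappa r)` within 0.03 up to twice the range and the
marginal variance within 10% at interior nodes.

## Temporal and seasonal structure

The AR(2) block is parameterized by partial autocorrelations
(`|pacf| < 1` guarantees stationarity) and scaled to unit marginal
variance, so the field's overall scale lives entirely in `tau(u)`;
without this convention the temporal innovation variance and the spatial
variance are confounded. The precision is built as the inverse of the
Toeplitz autocorrelation matrix (exact for the stationary likelihood)
with entries beyond bandwidth 2 — numerical noise — dropped. The
space-time precision is the Kronecker product `Q_t (x) Q_s`, i.e. a
separable covariance; non-separable interactions are out of scope.

The seasonal component penalizes 4-term moving sums: with structure
matrix `S = D'D` (`D` the moving-sum matrix) the log-density is
`((n-m+1)/2) log tau_s - (tau_s/2) x'Sx`. The null space of `S` is
exactly the period-4 patterns with zero cycle sum — the pure seasonal
signals the prior leaves free. A constant shift of the component *is*
penalized by `S`, which softly identifies the seasonal block against the
intercept; a weak ridge (1e-4) on the block makes the joint precision
strictly positive definite, and reported per-season effects are centred
to sum exactly to zero at summary time.

Model 1 runs the AR(2) over all 16 year-season steps (one temporal axis,
`t = 4 (year - first_year) + season_index` with seasons ordered Jilaal,
Gu, Hagaa, Deyr); model 2 runs the AR(2) over the 4 years and adds the
shared seasonal component over the 16-step axis. Model 1 answers "what
was the prevalence in each year-season"; model 2 isolates the seasonal
effect sizes.

## Inference

Hyperparameters `psi` (log tau / log kappa basis coefficients, AR partial
autocorrelations via tanh, seasonal and cluster log-precisions) are
estimated by empirical Bayes: Nelder-Mead maximization of the Laplace
approximation to the marginal posterior, with independent Gaussian priors
(SD 3) on the unconstrained scale centred at data-independent initial
values (prior range = a quarter of the domain, prior SD 0.5). The inner
problem — the latent mode at fixed `psi` — is solved by Newton iterations
with step halving (each step one sparse LU factorization of
`Q + A' W A`); the log-determinant of the prior uses the Kronecker
identity `logdet(Q_t (x) Q_s) = n_t logdet Q_s + n_v logdet Q_t`, so no
factorization of the big prior block is needed. Warm starts across
Nelder-Mead evaluations cut the inner iteration count substantially.

This is a mode-based Laplace approximation, not a full nested-integration
scheme: hyperparameter uncertainty is not propagated into the latent
summaries. On the synthetic studies used in the tests the effect is
within the reported intervals (95% intervals achieve nominal-or-better
coverage over 20 replicates), but posterior SDs should be read as
conditional on `psi-hat`.

The MCMC oracle is a preconditioned MALA sampler at fixed `psi`, dense
and capped at latent dimension 2000. Its preconditioner is the prior
precision plus the binomial curvature bound `A' diag(n/4) A` — fixed in
advance rather than taken from a fitted Hessian, so the sampler remains
an independent check of the Laplace mode. Step size adapts toward 0.574
acceptance during burn-in only; effective sample sizes use the
initial-positive-sequence estimator.

Prediction maps the posterior mean linear predictor through the inverse
logit; pixel SDs use the delta method `p(1-p) sd(eta)` by default, with
Monte-Carlo averaging over Gaussian draws of `eta` available when the
mean of the transformed distribution is wanted instead. Cluster effects
are set to zero at prediction (population-level surfaces). Pixels outside
the mesh are masked, not errors.

## Covariate selection

All `2^p` subsets (intercept always included) are fitted by a from-scratch
IRLS logistic regression and scored with
`BIC_gamma = D + k log(n_obs) + 2 gamma log C(p, k)`. The penalty term is
read as the log binomial coefficient: that is the form under which the
criterion corresponds to a uniform prior over models of each fixed size,
and the alternatives (`log(p k)`, `log(p^k)`) are undefined or wrong at
`k = 0`. `gamma` defaults to 1 (the full extended-BIC penalty) and is
configurable; `gamma = 0` recovers classical BIC. Ties break toward
smaller subsets, then lexicographic order. Covariates are standardized
before fitting for numerical stability, so reported coefficients are per
standard deviation; "significance" here means membership in the
EBIC-minimizing subset, with credible intervals from the spatial fit
reported descriptively.

## Risk classification and burden aggregation

WHO severity bands partition [0, 1] as [0, 0.05), [0.05, 0.10),
[0.10, 0.15), [0.15, 0.20], (0.20, 1]: the source guide writes "15-20%"
for critical and ">20%" for very critical, which closes the critical
interval at exactly 20%. Expected wasted children per pixel are
`prevalence x population`, kept real-valued through aggregation; rounding
and the "<50" small-cell convention are applied only in the formatted
report so no information is lost in machine output. Every populated pixel
must belong to exactly one zone or the aggregation errors out listing the
orphans. The dry-wet difference surface averages both seasons within each
regime (mean of Jilaal and Hagaa minus mean of Gu and Deyr), the
symmetric reading of a dry-minus-wet contrast.

## Hold-out validation

The 10% hold-out stratifies observations by (year-season) x spatial
block, the blocks from k-means on cluster coordinates with
`k = ceil(1/fraction)`, and draws proportionally from every non-empty
stratum by largest-remainder allocation, so the test size is exactly
`round(fraction N)` and held-out points are spread over space and time
rather than clumped. The specific de-clustering algorithm is a design
choice (recorded in the split metadata); any scheme that balances strata
would serve. Observed values are raw cluster proportions
`n_wasted/n_examined`; errors are predicted minus observed; correlation
is Pearson, reported as missing (never fabricated as 0) when either
vector is constant.

## Synthetic-data generator

The generator emulates the structure the analysis assumes: a planar
rectangular region in km split into three vertical-band zones; smooth
covariate surfaces (low-pass-filtered Gaussian noise) with rainfall
clipped to the observed monthly range 2-104 mm, EVI in [0, 1] and a 0/1
urban indicator on ~10% of pixels; uniformly scattered clusters; a latent
space-time field drawn from the same SPDE x AR(2) precision used in
inference (which makes parameter recovery a well-posed test); centred
seasonal offsets; iid cluster effects; binomial sampling.

Default conditions: 1066 clusters over 4 years x 4 seasons, intercept
`logit(0.21)` (matching the surveyed prevalence magnitude), covariate
log-odds effects (-0.20 rainfall, -0.24 EVI, +0.19 temperature, 0 for
distance-to-water and urbanization — the sign-and-null pattern reported
for the real surfaces, at per-SD magnitudes consistent with the published
odds ratios), spatial range 100 km with SD 0.35, AR partial
autocorrelations (0.6, 0.1) for persistent-but-fluctuating years,
seasonal offsets (+0.035, -0.035, +0.025, -0.025) — the published
seasonal log-odds ordering centred to sum to zero — and cluster SD 0.3.
Cluster sizes are uniform on 30-120 children; each cluster is observed at
one uniformly drawn year-season by default (matching the one-record-
per-cluster survey structure), with an `all_times` option for balanced
panels. Marginal simulated prevalence runs slightly above
`invlogit(beta_0)` because random effects enter inside the inverse logit
(Jensen); this is a property of the model, not a calibration error.

What the generator does not emulate: real geography and livelihood zones,
multi-stage sampling design effects beyond the iid cluster effect,
spatially varying seasonality, covariate measurement error, or shifts in
season onset between years. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the assumed model, not
the field validity of any particular map.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: regions of
100-200 km, meshes of 50-60 km edges (hundreds of vertices), 40-400
clusters, 20-replicate calibration studies. The same code paths scale to
survey-scale problems (1066 clusters, finer meshes) linearly in the
number of nonzeros of the joint precision. Key tolerances: inner Newton
stops at gradient norm 1e-6 (max 50 iterations, flagged if hit);
degenerate triangles, rank-deficient designs, non-stationary AR
parameters and out-of-range prevalences raise immediately rather than
propagate; complete separation in a GLM is flagged as non-convergence
and the subset scored +inf during selection.

## Known limitations

* Empirical-Bayes Laplace, not full hyperparameter integration; no skew
  correction.
* Separable space-time covariance; the seasonal component is global, not
  spatially varying.
* The CSV-grid raster dialect is the only raster backend; zone polygons
  are GeoJSON. Coordinates are planar km throughout — callers working in
  lon/lat should project first (an equirectangular projection at mean
  latitude is adequate at the spatial scales intended here).
* Fit serialization uses pickle; fits are runtime artifacts, not an
  interchange format.
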