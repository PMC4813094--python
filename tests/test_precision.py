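import numpy as np
import pytest
import scipy.sparse as sp

import wastingmap as wm
from wastingmap.meshfem import build_mesh, fem_matrices
from wastingmap.precision import (
    AR2Params,
    LatentLayout,
    intercept_basis,
    linear_basis,
    seasonal_structure,
)


@pytest.fixture(scope="module")
def fem_small():
    pts = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0], [50.0, 50.0]])
    mesh = build_mesh(pts, max_edge_km=15.0, buffer_km=10.0)
    return mesh, fem_matrices(mesh)


class TestParameterFields:
    def test_intercept_only_gives_constant_fields(self):
        basis = intercept_basis(10)
        tau, kappa = wm.evaluate_parameter_fields(basis, [0.7], [-0.3])
        np.testing.assert_allclose(tau, np.exp(0.7))
        np.testing.assert_allclose(kappa, np.exp(-0.3))

    def test_linear_basis_monotone_in_x(self, fem_small):
        mesh, _ = fem_small
        basis = linear_basis(mesh.vertices)
        _, kappa = wm.evaluate_parameter_fields(basis, [0.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        order = np.argsort(mesh.vertices[:, 0])
        assert np.all(np.diff(kappa[order]) >= -1e-12)

    def test_log_round_trip(self, fem_small):
        mesh, _ = fem_small
        basis = linear_basis(mesh.vertices)
        theta = np.array([0.5, -0.2, 0.1])
        tau, _ = wm.evaluate_parameter_fields(basis, theta, theta)
        np.testing.assert_allclose(np.log(tau), basis.B_tau @ theta, atol=1e-12)

    def test_non_finite_coefficients_rejected(self):
        basis = intercept_basis(5)
        with pytest.raises(ValueError):
            wm.evaluate_parameter_fields(basis, [np.nan], [0.0])


class TestSpatialPrecision:
    def test_symmetric_on_random_fields(self, fem_small):
        mesh, fem = fem_small
        rng = np.random.default_rng(0)
        tau = np.exp(rng.normal(0, 0.3, mesh.n_vertices))
        kappa = np.exp(rng.normal(-2, 0.3, mesh.n_vertices))
        Q = wm.spatial_precision(fem, tau, kappa)
        assert abs(Q - Q.T).max() < 1e-10

    def test_positive_definite(self, fem_small):
        mesh, fem = fem_small
        tau, kappa = wm.matern_parameters(30.0, 1.0)
        Q = wm.spatial_precision(
            fem, np.full(mesh.n_vertices, tau), np.full(mesh.n_vertices, kappa)
        )
        assert np.linalg.eigvalsh(Q.toarray()).min() > 0

    def test_rejects_nonpositive_fields(self, fem_small):
        mesh, fem = fem_small
        ones = np.ones(mesh.n_vertices)
        with pytest.raises(ValueError):
            wm.spatial_precision(fem, -ones, ones)


class TestAR2:
    def test_ar1_reduction_matches_hand_formula(self):
        rho = 0.55
        Q = wm.ar2_precision(12, AR2Params(rho, 0.0)).toarray()
        # stationary AR(1) precision with unit marginal variance
        expected = np.zeros((12, 12))
        s2 = 1.0 - rho**2
        for i in range(12):
            expected[i, i] = (1.0 + rho**2) / s2 if 0 < i < 11 else 1.0 / s2
        for i in range(11):
            expected[i, i + 1] = expected[i + 1, i] = -rho / s2
        np.testing.assert_allclose(Q, expected, atol=1e-10)

    def test_inverse_matches_yule_walker(self):
        params = AR2Params(0.6, 0.25)
        Q = wm.ar2_precision(16, params).toarray()
        cov = np.linalg.inv(Q)
        from scipy.linalg import toeplitz

        np.testing.assert_allclose(cov, toeplitz(params.autocorrelation(16)), atol=1e-8)

    def test_unit_marginal_variance(self):
        Q = wm.ar2_precision(10, AR2Params(0.4, -0.3)).toarray()
        np.testing.assert_allclose(np.diag(np.linalg.inv(Q)), 1.0, atol=1e-10)

    def test_nonstationary_parameters_rejected(self):
        with pytest.raises(ValueError):
            AR2Params(1.1, 0.0)
        with pytest.raises(ValueError):
            wm.ar2_precision(2, AR2Params(0.5, 0.0))


class TestSeasonal:
    def test_rank_is_n_minus_m_plus_1(self):
        model = seasonal_structure(16, 4)
        assert np.linalg.matrix_rank(model.S.toarray()) == 13

    def test_pure_seasonal_pattern_in_null_space(self):
        model = seasonal_structure(16, 4)
        cycle = np.array([1.0, -2.0, 3.0, -2.0])  # zero cycle sum
        x = np.tile(cycle, 4)
        assert float(x @ (model.S @ x)) == pytest.approx(0.0, abs=1e-12)

    def test_density_equals_direct_increment_sum(self):
        n, m, tau = 16, 4, 1.7
        model = seasonal_structure(n, m)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(n)
            direct = 0.5 * (n - m + 1) * np.log(tau) - 0.5 * tau * sum(
                x[i : i + m].sum() ** 2 for i in range(n - m + 1)
            )
            assert model.log_density(x, tau) == pytest.approx(direct, abs=1e-10)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError):
            seasonal_structure(4, 4)


class TestSpacetime:
    def test_dimensions(self):
        Qs = sp.identity(40, format="csr")
        Qt = wm.ar2_precision(16, AR2Params(0.5, 0.1))
        Qst = wm.spacetime_precision(Qs, Qt)
        assert Qst.shape == (640, 640)

    def test_kronecker_inverse_identity(self):
        rng = np.random.default_rng(5)
        B = rng.standard_normal((12, 12))
        Qs = sp.csr_matrix(B @ B.T + 12 * np.eye(12))
        Qt = wm.ar2_precision(5, AR2Params(0.5, 0.0))
        Qst = wm.spacetime_precision(Qs, Qt).toarray()
        expected = np.kron(
            np.linalg.inv(Qt.toarray()), np.linalg.inv(Qs.toarray())
        )
        np.testing.assert_allclose(np.linalg.inv(Qst), expected, atol=1e-8)

    def test_samples_show_ar_temporal_correlation(self):
        # sampled fields inherit the AR(2) lag-1 correlation at a fixed node
        from scipy.linalg import cholesky, solve_triangular

        params = AR2Params(0.6, 0.0)
        Qt = wm.ar2_precision(8, params).toarray()
        Qs = np.eye(5) * 4.0
        Ls, Lt = cholesky(Qs, lower=True), cholesky(Qt, lower=True)
        rng = np.random.default_rng(11)
        num = den = 0.0
        for _ in range(800):
            Z = rng.standard_normal((5, 8))
            W = solve_triangular(Ls.T, Z, lower=False)
            W = solve_triangular(Lt, W.T, lower=True, trans="T").T
            num += np.sum(W[0, :-1] * W[0, 1:])
            den += np.sum(W[0] ** 2)
        target = params.autocorrelation(2)[1]
        # pooled lag-1 moment ratio, corrected for the 7/8 pair count
        assert num / den * 8 / 7 == pytest.approx(target, abs=0.06)

    def test_dimension_cap(self):
        Qs = sp.identity(1000, format="csr")
        Qt = sp.identity(1000, format="csr")
        with pytest.raises(ValueError):
            wm.spacetime_precision(Qs, Qt)


class TestJointPrecision:
    def test_dimension_bookkeeping(self):
        layout = LatentLayout(
            n_fixed=3, n_spatial=20, n_time=4, n_seasonal=16, n_cluster=50
        )
        assert layout.total_dim == 1 + 3 + 80 + 16 + 50
        slices = [
            layout.intercept, layout.fixed, layout.spacetime,
            layout.seasonal, layout.cluster,
        ]
        covered = sum(s.stop - s.start for s in slices)
        assert covered == layout.total_dim
        assert slices[-1].stop == layout.total_dim

    def test_identity_blocks_give_identity(self):
        layout = LatentLayout(
            n_fixed=0, n_spatial=4, n_time=2, n_seasonal=0, n_cluster=0
        )
        Q = wm.assemble_joint_precision(
            layout, sp.identity(8, format="csr"), fixed_prior_prec=1.0
        )
        np.testing.assert_allclose(Q.toarray(), np.eye(9), atol=1e-12)

    def test_positive_definite_default_config(self, fem_small):
        mesh, fem = fem_small
        tau, kappa = wm.matern_parameters(30.0, 0.5)
        Qs = wm.spatial_precision(
            fem, np.full(mesh.n_vertices, tau), np.full(mesh.n_vertices, kappa)
        )
        Qt = wm.ar2_precision(4, AR2Params(0.5, 0.1))
        layout = LatentLayout(
            n_fixed=2, n_spatial=mesh.n_vertices, n_time=4,
            n_seasonal=16, n_cluster=30,
        )
        Q = wm.assemble_joint_precision(
            layout,
            wm.spacetime_precision(Qs, Qt),
            seasonal=seasonal_structure(16, 4),
            seasonal_log_prec=1.0,
            cluster_log_prec=1.0,
        )
        assert abs(Q - Q.T).max() < 1e-10
        np.linalg.cholesky(Q.toarray())  # raises if not PD
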