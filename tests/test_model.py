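import numpy as np
import pytest
from scipy.linalg import subspace_angles

from conftest import random_kernel, standardized_expr
from oracles import dense_marginal_loglik, dense_posterior_mean

from spatialpca import kernels, model
from spatialpca.io import CovariateTable, ExpressionMatrix
from spatialpca.model import fit, marginal_loglik, posterior_spatial_pcs, project_covariates


def random_orthonormal(rng, m, d):
    return np.linalg.qr(rng.normal(size=(m, d)))[0]


def projected(expr):
    return project_covariates(
        expr.values, CovariateTable.intercept_only(expr.n_locations)
    )


def simulate_from_model(rng, m, n, d, tau, sigma0_sq, gamma=0.5):
    """Draw (expr, kernel, W_true, Z_true) from the generative model."""
    coords = kernels.scale_coordinates(
        kernels.SpatialCoordinates(rng.uniform(0, 10, size=(n, 2)))
    )
    kern = kernels.lowrank_eigen(kernels.build_kernel(coords, gamma), 1.0)
    jitter = 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(sigma0_sq * tau * kern.K + jitter)
    Z = (chol @ rng.normal(size=(n, d))).T
    W = random_orthonormal(rng, m, d)
    Y = W @ Z + rng.normal(scale=np.sqrt(sigma0_sq), size=(m, n))
    expr = ExpressionMatrix(
        Y,
        gene_ids=[f"g{i}" for i in range(m)],
        location_ids=[f"s{i}" for i in range(n)],
        state="standardized",
    )
    return expr, kern, W, Z


class TestMarginalLoglik:
    def test_matches_dense_oracle_on_random_instances(self, rng):
        for _ in range(10):
            m = rng.integers(2, 7)
            n = rng.integers(3, 11)
            d = rng.integers(1, 3)
            expr = standardized_expr(rng.normal(size=(m, n)))
            kern = random_kernel(rng, n)
            W = random_orthonormal(rng, m, d)
            tau = 10 ** rng.uniform(-2, 2)
            s0 = 10 ** rng.uniform(-1, 1)
            got = marginal_loglik(expr, kern, W, tau, s0)
            want = dense_marginal_loglik(projected(expr), kern.K, W, tau, s0)
            assert abs(got - want) < 1e-8

    def test_zero_data_closed_form(self, rng):
        m, n, d = 3, 6, 2
        expr = ExpressionMatrix(
            np.zeros((m, n)),
            [f"g{i}" for i in range(m)],
            [f"s{i}" for i in range(n)],
            state="standardized",
        )
        kern = random_kernel(rng, n)
        W = random_orthonormal(rng, m, d)
        tau, s0 = 3.0, 0.5
        got = marginal_loglik(expr, kern, W, tau, s0)
        want = -0.5 * m * n * np.log(2 * np.pi * s0) - 0.5 * d * np.sum(
            np.log1p(tau * kern.eigvals)
        )
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_tau_zero_is_iid_gaussian_independent_of_kernel(self, rng):
        m, n, d = 4, 8, 2
        expr = standardized_expr(rng.normal(size=(m, n)))
        W = random_orthonormal(rng, m, d)
        s0 = 0.8
        lls = [
            marginal_loglik(expr, random_kernel(rng, n, gamma=g), W, 0.0, s0)
            for g in (0.3, 3.0)
        ]
        Yp = projected(expr)
        want = -0.5 * m * n * np.log(2 * np.pi * s0) - 0.5 * np.sum(Yp**2) / s0
        np.testing.assert_allclose(lls, want, rtol=1e-12)

    def test_rejects_invalid_parameters(self, rng):
        expr = standardized_expr(rng.normal(size=(3, 5)))
        kern = random_kernel(rng, 5)
        W = random_orthonormal(rng, 3, 1)
        with pytest.raises(ValueError):
            marginal_loglik(expr, kern, W, -1.0, 1.0)
        with pytest.raises(ValueError):
            marginal_loglik(expr, kern, W, 1.0, 0.0)
        with pytest.raises(ValueError, match="orthonormal"):
            marginal_loglik(expr, kern, 2 * W, 1.0, 1.0)


class TestFit:
    def test_identity_kernel_reduces_to_pca(self, rng):
        m, n, d = 6, 12, 2
        expr = standardized_expr(rng.normal(size=(m, n)))
        coords = kernels.SpatialCoordinates(rng.normal(size=(n, 2)), scaled=True)
        kern = kernels.lowrank_eigen(
            kernels.SpatialKernel(np.eye(n), coords, 1.0, kind="custom"), 1.0
        )
        res = fit(expr, kern, d=d)
        U = np.linalg.svd(projected(expr), full_matrices=False)[0][:, :d]
        np.testing.assert_allclose(np.abs(res.W), np.abs(U), atol=1e-6)

    def test_loglik_beats_black_box_candidates(self, rng):
        m, n, d = 5, 10, 2
        expr = standardized_expr(rng.normal(size=(m, n)))
        kern = random_kernel(rng, n)
        res = fit(expr, kern, d=d)
        best = -np.inf
        for _ in range(300):
            W = random_orthonormal(rng, m, d)
            tau = 10 ** rng.uniform(-6, 4)
            s0 = 10 ** rng.uniform(-2, 1)
            best = max(best, marginal_loglik(expr, kern, W, tau, s0))
        assert res.loglik >= best - 1e-4

    def test_loglik_beats_pca_baseline(self, rng):
        m, n, d = 8, 15, 3
        expr = standardized_expr(rng.normal(size=(m, n)))
        kern = random_kernel(rng, n)
        res = fit(expr, kern, d=d)
        Yp = projected(expr)
        W_pca = np.linalg.svd(Yp, full_matrices=False)[0][:, :d]
        s0_mm = np.mean(Yp**2)
        baseline = marginal_loglik(expr, kern, W_pca, 0.0, s0_mm)
        assert res.loglik >= baseline - 1e-8

    def test_null_data_gives_much_smaller_tau_than_spatial_data(self):
        # on iid noise the ML tau reflects only chance alignment and stays
        # far below the tau recovered from genuinely spatial data
        rng = np.random.default_rng(3)
        m, n, d = 100, 400, 3
        expr_null = standardized_expr(rng.normal(size=(m, n)))
        kern = random_kernel(rng, n, gamma=0.5)
        tau_null = fit(expr_null, kern, d=d).tau
        expr_sig, kern_sig, _, _ = simulate_from_model(
            rng, m, n, d, 10.0, 1.0, gamma=0.5
        )
        tau_sig = fit(expr_sig, kern_sig, d=d).tau
        assert tau_null <= 2.0
        assert tau_sig >= 5 * tau_null

    def test_tau_recovery_on_one_dimensional_strip(self, rng):
        # 30-location strip, tau = 5, m = 50: tau within a factor of 2 (median)
        estimates = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            expr, kern, _, _ = simulate_from_model(local, 50, 30, 1, 5.0, 1.0, gamma=1.0)
            estimates.append(fit(expr, kern, d=1).tau)
        med = np.median(estimates)
        assert 2.5 <= med <= 10.0

    def test_subspace_recovery(self, rng):
        # the recovered loading subspace tracks the truth close to the
        # statistical limit (~10 degrees at this size and signal strength)
        hits = 0
        for seed in range(10):
            local = np.random.default_rng(100 + seed)
            expr, kern, W_true, _ = simulate_from_model(
                local, 100, 400, 3, 10.0, 1.0, gamma=0.1
            )
            res = fit(expr, kern, d=3)
            angle = np.degrees(subspace_angles(res.W, W_true).max())
            hits += angle <= 15.0
        assert hits >= 9

    def test_permutation_consistency(self, rng):
        m, n, d = 5, 12, 2
        values = rng.normal(size=(m, n))
        expr = standardized_expr(values)
        coords = kernels.scale_coordinates(
            kernels.SpatialCoordinates(rng.normal(size=(n, 2)))
        )
        kern = kernels.lowrank_eigen(kernels.build_kernel(coords, 1.0), 1.0)
        res = fit(expr, kern, d=d)
        perm = rng.permutation(n)
        expr_p = ExpressionMatrix(
            expr.values[:, perm],
            expr.gene_ids,
            [expr.location_ids[i] for i in perm],
            state="standardized",
        )
        coords_p = kernels.SpatialCoordinates(coords.coords[perm], scaled=True)
        kern_p = kernels.lowrank_eigen(kernels.build_kernel(coords_p, 1.0), 1.0)
        res_p = fit(expr_p, kern_p, d=d)
        np.testing.assert_allclose(res_p.loglik, res.loglik, atol=1e-6)
        np.testing.assert_allclose(res_p.Z, res.Z[:, perm], atol=1e-6)

    def test_sign_convention_and_orthonormality(self, rng):
        expr = standardized_expr(rng.normal(size=(6, 14)))
        kern = random_kernel(rng, 14)
        res = fit(expr, kern, d=3)
        np.testing.assert_allclose(res.W.T @ res.W, np.eye(3), atol=1e-6)
        for col in res.W.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_d_out_of_range_rejected(self, rng):
        expr = standardized_expr(rng.normal(size=(4, 6)))
        kern = random_kernel(rng, 6)
        with pytest.raises(ValueError, match="d="):
            fit(expr, kern, d=4)


class TestPosterior:
    def test_matches_dense_conditioning_oracle(self, rng):
        for _ in range(5):
            m, n, d = 5, 8, 2
            expr = standardized_expr(rng.normal(size=(m, n)))
            kern = random_kernel(rng, n)
            res = fit(expr, kern, d=d)
            got = posterior_spatial_pcs(res, expr)
            want = dense_posterior_mean(
                projected(expr), kern.K, res.W, res.tau, res.sigma0_sq
            )
            np.testing.assert_allclose(got, want, atol=1e-8)
            np.testing.assert_allclose(res.Z, want, atol=1e-8)

    def test_tau_zero_collapses_to_prior_mean(self, rng):
        m, n, d = 4, 7, 2
        expr = standardized_expr(rng.normal(size=(m, n)))
        kern = random_kernel(rng, n)
        res = fit(expr, kern, d=d)
        res.tau = 0.0
        np.testing.assert_array_equal(posterior_spatial_pcs(res, expr), 0.0)

    def test_rank_one_kernel_gives_constant_factors(self, rng):
        m, n, d = 5, 9, 2
        expr = standardized_expr(rng.normal(size=(m, n)))
        coords = kernels.SpatialCoordinates(rng.normal(size=(n, 2)), scaled=True)
        kern = kernels.lowrank_eigen(
            kernels.SpatialKernel(np.ones((n, n)), coords, 1.0, kind="custom"), 1.0
        )
        res = fit(expr, kern, d=d)
        Z = posterior_spatial_pcs(res, expr)
        np.testing.assert_allclose(Z - Z[:, :1], 0.0, atol=1e-8)

    def test_posterior_shrinkage(self, rng):
        m, n, d = 6, 20, 3
        expr = standardized_expr(rng.normal(size=(m, n)))
        kern = random_kernel(rng, n)
        res = fit(expr, kern, d=d)
        raw = res.W.T @ projected(expr)
        assert (res.Z.var(axis=1) <= raw.var(axis=1) + 1e-12).all()
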