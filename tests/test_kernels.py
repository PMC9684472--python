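import numpy as np
import pytest

from oracles import bfs_hops
from conftest import standardized_expr

from spatialpca import kernels
from spatialpca.kernels import (
    SpatialCoordinates,
    SpatialKernel,
    block_kernel,
    build_kernel,
    delaunay_distance_matrix,
    delaunay_kernel,
    inverse_scale,
    lowrank_eigen,
    scale_coordinates,
    select_bandwidth,
    sheather_jones_bandwidth,
    silverman_bandwidth,
)


class TestScaleCoordinates:
    def test_unit_square_means_and_sds(self):
        pts = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float)
        scaled = scale_coordinates(SpatialCoordinates(pts))
        # hand calculation: mean 1 per axis, sample SD sqrt(4/3)
        np.testing.assert_allclose(scaled.axis_means, [1, 1])
        np.testing.assert_allclose(scaled.axis_sds, [np.sqrt(4 / 3)] * 2)
        np.testing.assert_allclose(scaled.coords.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.coords.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent_and_invertible(self, rng):
        pts = rng.normal(size=(20, 2)) * 5 + 3
        scaled = scale_coordinates(SpatialCoordinates(pts))
        assert scale_coordinates(scaled) is scaled
        np.testing.assert_allclose(inverse_scale(scaled), pts, atol=1e-12)

    def test_constant_axis_fails(self):
        pts = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            scale_coordinates(SpatialCoordinates(pts))


class TestBandwidth:
    def test_silverman_closed_form(self, rng):
        # standardized gene with sd 1 and IQR >= 1.34 at n = 10000
        n = 10000
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        got = silverman_bandwidth(x)
        q75, q25 = np.percentile(x, [75, 25])
        expected = 0.9 * min(1.0, (q75 - q25) / 1.34) * n ** (-0.2)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_median_of_two_genes(self, rng):
        values = rng.normal(size=(2, 6000))
        expr = standardized_expr(values)
        b1 = silverman_bandwidth(expr.values[0])
        b2 = silverman_bandwidth(expr.values[1])
        got = select_bandwidth(expr, method="silverman")
        np.testing.assert_allclose(got, 0.5 * (b1 + b2), rtol=1e-12)

    def test_auto_switches_at_large_sample_threshold(self, rng, monkeypatch):
        calls = []
        monkeypatch.setattr(
            kernels, "silverman_bandwidth", lambda x: calls.append("silverman") or 0.1
        )
        monkeypatch.setattr(
            kernels,
            "sheather_jones_bandwidth",
            lambda x: calls.append("sheather_jones") or 0.1,
        )
        expr = standardized_expr(rng.normal(size=(3, 10)))
        select_bandwidth(expr, n=5001, method="auto")
        assert set(calls) == {"silverman"}
        calls.clear()
        select_bandwidth(expr, n=5000, method="auto")
        assert set(calls) == {"sheather_jones"}

    def test_sheather_jones_close_to_gaussian_optimum(self, rng):
        # for a normal sample the SJ bandwidth approaches 1.059 sigma n^(-1/5)
        x = rng.normal(size=2000)
        got = sheather_jones_bandwidth(x)
        expected = 1.0592 * x.std(ddof=1) * 2000 ** (-0.2)
        assert abs(got - expected) / expected < 0.15

    def test_all_degenerate_genes_is_an_error(self):
        from spatialpca.io import ExpressionMatrix

        degen = ExpressionMatrix(
            np.zeros((1, 50)), ["g0"], [f"s{i}" for i in range(50)], state="standardized"
        )
        with pytest.raises(ValueError, match="bandwidth"):
            select_bandwidth(degen, method="silverman")


class TestBuildKernel:
    def test_unit_diagonal_and_closed_form_offdiag(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        coords = scale_coordinates(SpatialCoordinates(pts))
        gamma = 2.0
        kern = build_kernel(coords, gamma)
        np.testing.assert_allclose(np.diag(kern.K), 1.0)
        d2 = np.sum((coords.coords[0] - coords.coords[1]) ** 2)
        np.testing.assert_allclose(kern.K[0, 1], np.exp(-d2 / gamma), rtol=1e-12)

    def test_two_points_at_distance_sqrt_gamma(self):
        coords = SpatialCoordinates(np.array([[0.0, 0.0], [1.0, 0.0]]), scaled=True)
        kern = build_kernel(coords, gamma=1.0)  # d^2 == gamma
        np.testing.assert_allclose(kern.K[0, 1], np.exp(-1.0), rtol=1e-12)

    def test_large_gamma_limit_is_all_ones(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(6, 2))))
        kern = build_kernel(coords, gamma=1e12)
        np.testing.assert_allclose(kern.K, 1.0, atol=1e-9)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(15, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        k1 = build_kernel(SpatialCoordinates(pts, scaled=True), 1.3).K
        k2 = build_kernel(SpatialCoordinates(pts @ rot.T, scaled=True), 1.3).K
        np.testing.assert_allclose(k1, k2, atol=1e-10)

    def test_positive_semidefinite_up_to_jitter(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(40, 2))))
        kern = build_kernel(coords, 0.5)
        vals = np.linalg.eigvalsh(kern.K)
        assert vals.min() >= -1e-8 * vals.max()

    def test_sparse_cutoff_zeroes_small_entries(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(30, 2))))
        dense = build_kernel(coords, 0.05, sparse_cutoff=0.0).K
        cut = build_kernel(coords, 0.05, sparse_cutoff=1e-3).K
        assert (cut[dense < 1e-3] == 0).all()
        # eigenvalues move by at most n * cutoff
        dv = np.linalg.eigvalsh(dense)
        cv = np.linalg.eigvalsh(cut)
        assert np.max(np.abs(dv - cv)) <= 30 * 1e-3

    def test_histology_pseudo_dimension_reduces_similarity(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(10, 2))))
        histology = rng.normal(size=(10, 2))
        plain = build_kernel(coords, 1.0).K
        with_h = build_kernel(coords, 1.0, histology=histology).K
        off = ~np.eye(10, dtype=bool)
        assert (with_h[off] <= plain[off] + 1e-12).all()


class TestDelaunay:
    def test_triangle_all_hops_one(self):
        coords = SpatialCoordinates(
            np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]), scaled=True
        )
        hops = delaunay_distance_matrix(coords)
        assert np.array_equal(np.diag(hops), [0, 0, 0])
        off = hops[~np.eye(3, dtype=bool)]
        assert (off == 1).all()

    def test_hops_match_bfs_oracle(self, rng):
        pts = rng.normal(size=(25, 2))
        coords = SpatialCoordinates(pts, scaled=True)
        hops = delaunay_distance_matrix(coords)
        # rebuild adjacency from hop-1 pairs and re-derive all hops with BFS
        adj = [set(np.where(hops[i] == 1)[0]) for i in range(25)]
        np.testing.assert_array_equal(hops, bfs_hops(adj, 25))

    def test_unit_square_diagonal_consistency(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        hops = delaunay_distance_matrix(SpatialCoordinates(pts, scaled=True))
        # one diagonal of the square is triangulated: opposite corners are at
        # hop 1 or 2 depending on which diagonal was chosen
        assert hops[0, 3] in (1, 2)
        assert hops[1, 2] in (1, 2)
        assert hops[0, 3] + hops[1, 2] == 3

    def test_kernel_from_hops(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        kern = delaunay_kernel(SpatialCoordinates(pts, scaled=True), gamma=2.0)
        np.testing.assert_allclose(np.diag(kern.K), 1.0)
        np.testing.assert_allclose(
            kern.K[0, 1], np.exp(-1.0 / 2.0), rtol=1e-12
        )


class TestLowrankEigen:
    def test_rank_one_kernel(self):
        coords = SpatialCoordinates(np.zeros((5, 2)) + np.arange(10).reshape(5, 2), scaled=True)
        kern = SpatialKernel(K=np.ones((5, 5)), coords=coords, gamma=1.0, kind="custom")
        out = lowrank_eigen(kern, 0.9)
        assert out.rank == 1
        np.testing.assert_allclose(out.eigvals[0], 5.0)

    def test_identity_kernel_equal_eigenvalues(self):
        coords = SpatialCoordinates(np.arange(20).reshape(10, 2), scaled=True)
        kern = SpatialKernel(K=np.eye(10), coords=coords, gamma=1.0, kind="custom")
        out = lowrank_eigen(kern, 0.9)
        assert out.rank == 9

    def test_reconstruction_error_bound(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(30, 2))))
        kern = build_kernel(coords, 0.8)
        out = lowrank_eigen(kern, 0.9)
        approx = (out.eigvecs * out.eigvals) @ out.eigvecs.T
        rel = np.linalg.norm(kern.K - approx) / np.linalg.norm(kern.K)
        assert rel <= np.sqrt(1 - out.variance_fraction) + 1e-8
        assert out.variance_fraction >= 0.9

    def test_eigenvalues_descending_and_orthonormal(self, rng):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(25, 2))))
        out = lowrank_eigen(build_kernel(coords, 1.0), 0.95)
        assert (np.diff(out.eigvals) <= 1e-12).all()
        gram = out.eigvecs.T @ out.eigvecs
        np.testing.assert_allclose(gram, np.eye(out.rank), atol=1e-8)


class TestBlockKernel:
    def _kernel(self, rng, n, gamma=1.0):
        coords = scale_coordinates(SpatialCoordinates(rng.normal(size=(n, 2))))
        return lowrank_eigen(build_kernel(coords, gamma), 1.0)

    def test_cross_block_entries_zero(self, rng):
        blocks = [self._kernel(rng, 6), self._kernel(rng, 4)]
        out = block_kernel(blocks)
        assert out.kind == "block"
        assert (out.K[:6, 6:] == 0).all()
        np.testing.assert_array_equal(out.K[:6, :6], blocks[0].K)

    def test_eigenvalue_multiset_is_union(self, rng):
        blocks = [self._kernel(rng, 6), self._kernel(rng, 5)]
        out = block_kernel(blocks)
        expected = np.sort(np.concatenate([blocks[0].eigvals, blocks[1].eigvals]))
        np.testing.assert_allclose(np.sort(out.eigvals), expected, atol=1e-10)
        # eigenvectors remain orthonormal and reconstruct the block matrix
        approx = (out.eigvecs * out.eigvals) @ out.eigvecs.T
        np.testing.assert_allclose(approx, out.K, atol=1e-8)

    def test_single_block_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            block_kernel([self._kernel(rng, 5)])
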