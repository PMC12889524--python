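"""Eigensystem and spectral descriptor operations."""

import numpy as np
import pytest
import scipy.sparse as sp

from spectropath import (
    AllZeroEnergyError,
    InsufficientBandsError,
    band_energies,
    eigendecompose,
    fractal_slope,
    heat_kernel_signature,
    lacunarity,
    normalized_laplacian,
    renyi_dimension,
    slepian_concentration,
    spectral_coefficients,
    spectral_embedding,
    wavelet_energy,
)
from spectropath.spectral import band_distribution
from conftest import random_weight_matrix

K2_W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))


def random_eigensystem(n, seed):
    rng = np.random.default_rng(seed)
    W = random_weight_matrix(n, rng, density=0.3)
    return eigendecompose(normalized_laplacian(W), n), rng


class TestEigendecompose:
    def test_k2_closed_form(self):
        eig = eigendecompose(normalized_laplacian(K2_W), 2)
        assert np.allclose(eig.lambdas, [0.0, 2.0], atol=1e-12)
        assert np.allclose(np.abs(eig.vectors[:, 0]), 1 / np.sqrt(2))

    def test_path3_spectrum(self):
        W = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float))
        eig = eigendecompose(normalized_laplacian(W), 3)
        assert np.allclose(eig.lambdas, [0, 1, 2], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_full_basis_orthonormal(self, seed):
        eig, _ = random_eigensystem(20, seed)
        G = eig.vectors.T @ eig.vectors
        assert np.abs(G - np.eye(20)).max() < 1e-8

    def test_sign_convention_deterministic(self):
        eig1, _ = random_eigensystem(15, 4)
        eig2, _ = random_eigensystem(15, 4)
        assert np.array_equal(eig1.vectors, eig2.vectors)
        idx = np.abs(eig1.vectors).argmax(axis=0)
        assert (eig1.vectors[idx, np.arange(eig1.K)] > 0).all()

    def test_sparse_path_matches_dense(self, small_graph):
        eig_sparse = eigendecompose(small_graph.laplacian, 10)
        eig_dense = eigendecompose(small_graph.laplacian.toarray(), 10)
        assert np.allclose(eig_sparse.lambdas, eig_dense.lambdas, atol=1e-8)


class TestSpectralCoefficients:
    def test_eigenvector_projects_to_unit_coordinate(self):
        eig, _ = random_eigensystem(12, 0)
        a = spectral_coefficients(eig.vectors, eig.vectors[:, [0]])
        expected = np.zeros(12)
        expected[0] = 1.0
        assert np.allclose(a[0], expected, atol=1e-10)

    def test_zero_signal(self):
        eig, _ = random_eigensystem(8, 1)
        assert not spectral_coefficients(eig.vectors, np.zeros((8, 2))).any()

    @pytest.mark.parametrize("seed", range(3))
    def test_parseval_at_full_rank(self, seed):
        eig, rng = random_eigensystem(25, seed)
        x = rng.normal(size=(25, 4))
        a = spectral_coefficients(eig.vectors, x)
        assert np.allclose((a**2).sum(axis=1), (x**2).sum(axis=0), rtol=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            spectral_coefficients(np.eye(3), np.zeros((4, 2)))


class TestHeatKernelSignature:
    def test_single_node(self):
        from spectropath.spectral import EigenSystem

        eig = EigenSystem(np.array([0.0]), np.array([[1.0]]))
        h = heat_kernel_signature(eig, [0.1, 1.0, 10.0], lambda_cutoff=None)
        assert np.allclose(h, 1.0)

    def test_k2_closed_form(self):
        eig = eigendecompose(normalized_laplacian(K2_W), 2)
        ts = np.array([0.0, 0.5, 2.0, 50.0])
        h = heat_kernel_signature(eig, ts, lambda_cutoff=None)
        expected = 0.5 + 0.5 * np.exp(-2 * ts)
        assert np.allclose(h, expected[:, None])

    @pytest.mark.parametrize("seed", range(3))
    def test_heat_trace_identity(self, seed):
        eig, _ = random_eigensystem(30, seed)
        ts = [0.3, 1.0, 3.0]
        h = heat_kernel_signature(eig, ts, lambda_cutoff=None)
        trace = np.exp(-np.outer(ts, eig.lambdas)).sum(axis=1)
        assert np.allclose(h.sum(axis=1), trace, atol=1e-8)


class TestWaveletEnergy:
    def test_t0_is_total_energy(self):
        eig, rng = random_eigensystem(10, 2)
        a = rng.normal(size=(3, 10))
        E = wavelet_energy(eig, a, [0.0])
        assert np.allclose(E[:, 0], (a**2).sum(axis=1))

    def test_single_eigenpair_closed_form(self):
        from spectropath.spectral import EigenSystem

        eig = EigenSystem(np.array([2.0]), np.ones((1, 1)))
        E = wavelet_energy(eig, np.array([[3.0]]), [0.5])
        assert E[0, 0] == pytest.approx(9 * np.exp(-2.0))

    def test_monotone_in_time(self):
        eig, rng = random_eigensystem(15, 3)
        a = rng.normal(size=(2, 15))
        E = wavelet_energy(eig, a, [0.1, 0.5, 1.0, 4.0])
        assert (np.diff(E, axis=1) <= 1e-12).all()


class TestSlepian:
    def test_identity_region(self):
        eig, _ = random_eigensystem(10, 4)
        assert np.allclose(slepian_concentration(eig.vectors, np.eye(10)), 1.0)

    def test_indicator_bounds(self):
        eig, rng = random_eigensystem(12, 5)
        M = np.diag((rng.random(12) < 0.5).astype(float))
        C = slepian_concentration(eig.vectors, M)
        assert (C >= -1e-12).all() and (C <= 1 + 1e-12).all()

    def test_k2_adjacency(self):
        eig = eigendecompose(normalized_laplacian(K2_W), 2)
        C = slepian_concentration(eig.vectors, K2_W.toarray())
        assert C[0] == pytest.approx(1.0)  # u1 = (1,1)/sqrt(2)


class TestBandsAndFractal:
    def test_one_hot_and_uniform(self):
        lams = np.array([0.1, 0.12, 0.15])
        E = band_energies(np.array([[1.0, 2.0, 3.0]]), lams, B=8)
        p = band_distribution(E)
        assert p[0] == 1.0 and p[1:].sum() == 0.0
        assert np.allclose(band_distribution(np.ones(6)), 1 / 6)

    @pytest.mark.parametrize("seed", range(3))
    def test_energy_conservation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 30))
        lams = rng.uniform(0, 2, 30)
        E = band_energies(a, lams, B=8, per_channel=True)
        assert np.allclose(E.sum(axis=1), (a**2).sum(axis=1), rtol=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(AllZeroEnergyError):
            band_energies(np.zeros((2, 5)), np.linspace(0, 2, 5), B=4)

    def test_fractal_slope_power_law(self):
        k = np.arange(1, 9)
        assert fractal_slope(k**-2.0) == pytest.approx(-2.0, abs=1e-9)
        assert fractal_slope(np.ones(8)) == pytest.approx(0.0, abs=1e-12)
        assert fractal_slope(np.array([1.0, 8.0])) == pytest.approx(3.0)

    def test_fractal_slope_insufficient(self):
        with pytest.raises(InsufficientBandsError):
            fractal_slope(np.array([1.0, 0.0]))

    def test_renyi_closed_forms(self):
        degenerate = np.zeros(8)
        degenerate[0] = 1.0
        for q in (2.0, 3.0):
            assert renyi_dimension(degenerate, q) == pytest.approx(0.0)
        uniform = np.full(8, 1 / 8)
        for q in (1.0, 2.0, 3.0):
            assert renyi_dimension(uniform, q) == pytest.approx(-1.0)

    def test_renyi_continuous_at_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.dirichlet(np.ones(8))
            assert abs(renyi_dimension(p, 1.001) - renyi_dimension(p, 1.0)) < 1e-3

    def test_renyi_monotone_after_sign_normalization(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.dirichlet(rng.uniform(0.2, 3.0, 8))
            conventional = [-renyi_dimension(p, q) for q in (1.0, 2.0, 3.0)]
            assert conventional[0] >= conventional[1] - 1e-10
            assert conventional[1] >= conventional[2] - 1e-10

    def test_lacunarity(self):
        assert np.allclose(lacunarity(np.full(8, 3.0), 3), 1.0)
        assert lacunarity(np.array([0.0, 2.0]), 2)[0] == pytest.approx(2.0)
        rng = np.random.default_rng(2)
        assert (lacunarity(rng.random(10), 4) >= 1.0).all()
        assert np.allclose(lacunarity(np.zeros(5), 3), 1.0)


class TestSpectralEmbedding:
    def test_k2_first_axis_degenerate(self):
        eig = eigendecompose(normalized_laplacian(K2_W), 2)
        pts = spectral_embedding(eig, K_embed=1)
        assert abs(pts[0, 0] - pts[1, 0]) < 1e-12

    def test_coefficient_scaling(self):
        eig, rng = random_eigensystem(10, 6)
        a = rng.normal(size=(3, 10))
        pts = spectral_embedding(eig, a, K_embed=4, scale_by_coefficients=True)
        scale = np.sqrt((a[:, :4] ** 2).sum(axis=0))
        assert np.allclose(pts, eig.vectors[:, :4] * scale)
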