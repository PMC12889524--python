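import numpy as np
import pytest
import scipy.sparse as sp

from spectropath import GridSpec, MorphologyParams, build_grid_graph, generate_patch


@pytest.fixture(scope="session")
def small_patch():
    """One deterministic 128x128 synthetic patch."""
    return generate_patch(MorphologyParams(patch_size=128, nuclei_density=60.0), seed=7)


@pytest.fixture(scope="session")
def small_graph(small_patch):
    return build_grid_graph(small_patch, GridSpec(grid_size=16))


@pytest.fixture(scope="session")
def connected_graph():
    """Fully-tissued noisy patch -> connected complete-grid graph.

    Generic Gaussian weights give a simple Laplacian spectrum, the
    precondition for descriptor permutation invariance.
    """
    rng = np.random.default_rng(5)
    patch = np.clip(rng.normal(110, 25, size=(64, 64, 3)), 0, 255).astype(np.uint8)
    return build_grid_graph(patch, GridSpec(grid_size=8))


def random_weight_matrix(n, rng, density=0.3):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(A, 1)
    W = W + W.T
    return sp.csr_matrix(W)
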