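"""Assembly of spectral descriptor blocks into a fixed-length vector.

Per-node quantities (the heat kernel signature) are pooled to
(mean, std, min, max) over nodes so the vector length is independent of how
many grid cells held tissue. Under the default configuration the vector is
exactly 184 floats:

    hks             4 times x 4 node statistics          = 16
    wavelet_energy  8 channels x 5 times (incl. t=0, the total captured
                    band energy per channel)             = 40
    slepian         C_j for j = 1..32 (zero padded) + 4  = 36
    fractal         per channel: slope + D_{1,2,3} + 6 lacunarity windows = 80
    persistence     per dim 0/1: total, entropy, count, mean, max, std    = 12

PCA reduction to 25 dimensions (fit over a dataset of such vectors) follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .errors import AllZeroEnergyError, InsufficientBandsError, MissingBlockError
from .patch_graph import FEATURE_NAMES, TissueGraph
from .persistence import (
    persistence_entropy,
    subsample_points,
    vietoris_rips_persistence,
)
from .spectral import (
    EigenSystem,
    band_energies,
    eigendecompose,
    fractal_slope,
    heat_kernel_signature,
    lacunarity,
    renyi_dimension,
    slepian_concentration,
    spectral_coefficients,
    spectral_embedding,
    wavelet_energy,
)

BLOCK_ORDER = ("hks", "wavelet_energy", "slepian", "fractal", "persistence")


@dataclass(frozen=True)
class DescriptorConfig:
    """Knobs of the descriptor pipeline; defaults give a 184-float vector."""

    n_eigenpairs: int = 128
    hks_times: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    hks_lambda_cutoff: float | None = 0.02
    wavelet_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    slepian_j: int = 32
    slepian_use_adjacency: bool = False
    n_bands: int = 8
    renyi_q: tuple[float, ...] = (1.0, 2.0, 3.0)
    lacunarity_window: int = 3
    k_embed: int = 8
    persistence_max_points: int = 64
    persistence_eps_quantile: float = 0.95
    standardize_channels: bool = True
    blocks: tuple[str, ...] = BLOCK_ORDER
    pca_dim: int = 25


@dataclass
class DescriptorVector:
    """Named concatenation of descriptor blocks."""

    values: np.ndarray
    block_index: dict[str, tuple[int, int]]
    names: tuple[str, ...]

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, name: str) -> np.ndarray:
        off, length = self.block_index[name]
        return self.values[off : off + length]


def _pool(values: np.ndarray) -> np.ndarray:
    """(mean, std, min, max) over the node axis."""
    return np.array([values.mean(), values.std(), values.min(), values.max()])


def _standardized_channels(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def compute_blocks(
    graph: TissueGraph,
    config: DescriptorConfig = DescriptorConfig(),
    eig: EigenSystem | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[str, ...]]]:
    """All enabled descriptor blocks for one tissue graph.

    Returns (block values, per-entry names). Deterministic: the eigensystem
    sign convention and the lexicographic persistence subsample make every
    block invariant to node relabeling (for simple spectra). A precomputed
    eigensystem may be passed to avoid repeating the decomposition.
    """
    if eig is None:
        K = min(config.n_eigenpairs, graph.n_nodes)
        eig = eigendecompose(graph.laplacian, K)
    X = graph.features
    Xs = _standardized_channels(X) if config.standardize_channels else X
    coeffs = spectral_coefficients(eig.vectors, Xs)

    blocks: dict[str, np.ndarray] = {}
    names: dict[str, tuple[str, ...]] = {}

    if "hks" in config.blocks:
        hks = heat_kernel_signature(eig, config.hks_times, config.hks_lambda_cutoff)
        vals, nm = [], []
        for t, row in zip(config.hks_times, hks):
            vals.append(_pool(row))
            nm += [f"hks_t{t:g}_{s}" for s in ("mean", "std", "min", "max")]
        blocks["hks"] = np.concatenate(vals)
        names["hks"] = tuple(nm)

    if "wavelet_energy" in config.blocks:
        E = wavelet_energy(eig, coeffs, config.wavelet_times)  # (C, T)
        blocks["wavelet_energy"] = E.ravel()
        names["wavelet_energy"] = tuple(
            f"wavelet_{ch}_t{t:g}" for ch in FEATURE_NAMES for t in config.wavelet_times
        )

    if "slepian" in config.blocks:
        if config.slepian_use_adjacency:
            M = graph.weights
        else:
            # diagonal indicator of high-curvature nodes (top-quartile laplacian_var)
            lv = X[:, FEATURE_NAMES.index("laplacian_var")]
            thresh = np.quantile(lv, 0.75)
            M = sp.diags((lv >= thresh).astype(np.float64))
        C = slepian_concentration(eig.vectors, M)
        J = config.slepian_j
        padded = np.zeros(J)
        padded[: min(J, C.shape[0])] = C[:J]
        blocks["slepian"] = np.concatenate([padded, _pool(C)])
        names["slepian"] = tuple(f"slepian_C{j + 1}" for j in range(J)) + tuple(
            f"slepian_{s}" for s in ("mean", "std", "min", "max")
        )

    if "fractal" in config.blocks:
        blocks["fractal"], names["fractal"] = _fractal_block(coeffs, eig, config)

    if "persistence" in config.blocks:
        k_embed = min(config.k_embed, eig.K)
        pts = spectral_embedding(eig, coeffs, k_embed)
        pts = subsample_points(pts, config.persistence_max_points)
        diff = pts[:, None, :] - pts[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
        if pts.shape[0] > 1:
            eps = float(
                np.quantile(D[np.triu_indices(pts.shape[0], k=1)], config.persistence_eps_quantile)
            )
        else:
            eps = 0.0
        diagram = vietoris_rips_persistence(D, eps_max=eps, max_dim=1)
        vals = []
        for dim in (0, 1):
            ell = diagram.finite_lifetimes(dim)
            sub = type(diagram)(bars=[b for b in diagram.bars if b[0] == dim])
            total, H = persistence_entropy(sub)
            vals += [
                total,
                H,
                float(ell.size),
                float(ell.mean()) if ell.size else 0.0,
                float(ell.max()) if ell.size else 0.0,
                float(ell.std()) if ell.size else 0.0,
            ]
        blocks["persistence"] = np.array(vals)
        names["persistence"] = tuple(
            f"pers_h{dim}_{s}"
            for dim in (0, 1)
            for s in ("total_life", "entropy", "n_bars", "mean_life", "max_life", "std_life")
        )

    return blocks, names


def _fractal_block(coeffs, eig: EigenSystem, config: DescriptorConfig):
    B, w = config.n_bands, config.lacunarity_window
    n_win = B - w + 1
    vals, nm = [], []
    try:
        E_all = band_energies(coeffs, eig.lambdas, B, per_channel=True)
    except AllZeroEnergyError:
        E_all = np.zeros((coeffs.shape[0], B))
    for c, ch in enumerate(FEATURE_NAMES):
        E = E_all[c]
        total = E.sum()
        try:
            slope = fractal_slope(E)
        except InsufficientBandsError:
            slope = 0.0
        if total > 0:
            p = E / total
            dq = [renyi_dimension(p, q, B) for q in config.renyi_q]
            lac = lacunarity(E, w)
        else:
            dq = [0.0] * len(config.renyi_q)
            lac = np.zeros(n_win)
        vals.append(np.concatenate([[slope], dq, lac]))
        nm += (
            [f"fractal_{ch}_slope"]
            + [f"fractal_{ch}_D{q:g}" for q in config.renyi_q]
            + [f"fractal_{ch}_lac{i + 1}" for i in range(n_win)]
        )
    return np.concatenate(vals), tuple(nm)


def assemble_descriptor(
    blocks: dict[str, np.ndarray],
    config: DescriptorConfig = DescriptorConfig(),
    names: dict[str, tuple[str, ...]] | None = None,
) -> DescriptorVector:
    """Concatenate blocks in canonical order into one DescriptorVector."""
    values, index, all_names = [], {}, []
    offset = 0
    for name in BLOCK_ORDER:
        if name not in config.blocks:
            continue
        if name not in blocks:
            raise MissingBlockError(f"block '{name}' enabled but not supplied")
        v = np.asarray(blocks[name], dtype=np.float64).ravel()
        index[name] = (offset, v.shape[0])
        offset += v.shape[0]
        values.append(v)
        if names and name in names:
            all_names.extend(names[name])
        else:
            all_names.extend(f"{name}_{i}" for i in range(v.shape[0]))
    return DescriptorVector(np.concatenate(values), index, tuple(all_names))


def compute_descriptor(
    graph: TissueGraph, config: DescriptorConfig = DescriptorConfig()
) -> DescriptorVector:
    """Full descriptor for one tissue graph."""
    blocks, names = compute_blocks(graph, config)
    return assemble_descriptor(blocks, config, names)


@dataclass
class PCAModel:
    """Centered orthonormal projection onto the top principal axes."""

    mean: np.ndarray
    components: np.ndarray  # (out_dim, in_dim), orthonormal rows
    explained_variance: np.ndarray  # non-increasing


def fit_pca(features: np.ndarray, out_dim: int = 25) -> PCAModel:
    """Fit a PCA reduction; warns when trailing components are rank-deficient."""
    features = np.asarray(features, dtype=np.float64)
    n, p = features.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    out_dim = min(out_dim, n - 1, p)
    model = PCA(n_components=out_dim, svd_solver="full")
    model.fit(features)
    ev = model.explained_variance_
    if ev.size and ev[-1] < 1e-12 * max(ev[0], 1.0):
        warnings.warn("trailing principal components have ~zero variance", stacklevel=2)
    return PCAModel(model.mean_.copy(), model.components_.copy(), ev.copy())


def apply_pca(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    return (rows - model.mean) @ model.components.T
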