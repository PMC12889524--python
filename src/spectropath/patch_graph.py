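"""Grid-graph construction from stained image patches.

An RGB patch is divided into a fixed ``grid_size`` x ``grid_size`` grid of
cells. Cells whose fraction of tissue pixels (dark, non-background pixels)
reaches ``tissue_threshold`` become graph nodes carrying an 8-channel
morphological feature vector. Nodes are joined to their four immediate grid
neighbours with Gaussian edge weights

    w_ij = exp(-||p_i - p_j||^2 / (2 sigma_p^2)) * exp(-(I_i - I_j)^2 / (2 sigma_I^2))

and the symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2} is the
operator every downstream spectral descriptor is built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from skimage.color import rgb2hed, rgb2hsv
from skimage.filters import laplace, sobel

from .errors import EmptyGraphError

FEATURE_NAMES = (
    "gray_mean",
    "entropy",
    "laplacian_var",
    "h_mean",
    "e_mean",
    "saturation",
    "sobel_var",
    "tissue_boundary_ratio",
)

_ENTROPY_BINS = 32


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and tissue-detection parameters.

    sigma_I may be the string "auto", meaning the standard deviation of the
    gray_mean channel over valid nodes (1.0 when that is zero).
    """

    grid_size: int = 64
    tissue_threshold: float = 0.20
    tissue_luminance_cutoff: float = 220.0
    sigma_p: float | str = "auto"  # auto -> one cell spacing in pixels
    sigma_I: float | str = "auto"
    use_feature_vector_intensity: bool = False

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if not 0 < self.tissue_threshold <= 1:
            raise ValueError("tissue_threshold must lie in (0, 1]")


@dataclass
class TissueGraph:
    """Weighted grid graph over valid tissue cells plus its Laplacian."""

    node_ids: dict[tuple[int, int], int]
    positions: np.ndarray  # (N, 2) cell centres, (x, y) pixel units, y down
    features: np.ndarray  # (N, 8), columns ordered as FEATURE_NAMES
    weights: sp.csr_matrix  # symmetric, zero diagonal
    laplacian: sp.csr_matrix
    feature_names: tuple[str, ...] = FEATURE_NAMES
    grid_shape: tuple[int, int] = (0, 0)

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


def validate_patch(patch: np.ndarray, grid_size: int = 1) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"patch must be HxWx3, got {patch.shape}")
    if patch.shape[0] < grid_size or patch.shape[1] < grid_size:
        raise ValueError("patch smaller than the grid")
    if patch.min() < 0 or patch.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return patch


def segment_tissue_mask(patch: np.ndarray, spec: GridSpec = GridSpec()) -> np.ndarray:
    """Boolean mask of tissue pixels: mean-RGB luminance below the cutoff.

    Stained tissue is dark on a near-white background, so a luminance
    threshold (default 220) separates the two.
    """
    patch = validate_patch(patch)
    luminance = patch.astype(np.float64).mean(axis=2)
    return luminance < spec.tissue_luminance_cutoff


def edge_weight(
    p_i: np.ndarray,
    p_j: np.ndarray,
    I_i: float | np.ndarray,
    I_j: float | np.ndarray,
    sigma_p: float,
    sigma_I: float,
) -> float:
    """Gaussian edge weight in (0, 1], separable in position and intensity."""
    if sigma_p <= 0 or sigma_I <= 0:
        raise ValueError("sigmas must be positive")
    dp2 = float(np.sum((np.asarray(p_i, dtype=float) - np.asarray(p_j, dtype=float)) ** 2))
    dI2 = float(np.sum((np.asarray(I_i, dtype=float) - np.asarray(I_j, dtype=float)) ** 2))
    return float(np.exp(-dp2 / (2.0 * sigma_p**2)) * np.exp(-dI2 / (2.0 * sigma_I**2)))


def normalized_laplacian(W: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """L = I - D^{-1/2} W D^{-1/2}; isolated nodes keep L_ii = 1.

    Zero-degree rows use the convention D^{-1/2} = 0, so an isolated node
    contributes a unit diagonal entry (eigenvalue 1) instead of a NaN.
    """
    W = sp.csr_matrix(W, dtype=np.float64)
    n = W.shape[0]
    d = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    Dinv = sp.diags(d_isqrt)
    L = sp.identity(n, format="csr") - Dinv @ W @ Dinv
    # symmetrise away round-off
    L = (L + L.T) * 0.5
    return sp.csr_matrix(L)


def _block_view(arr: np.ndarray, gh: int, gw: int, cs_h: int, cs_w: int) -> np.ndarray:
    """Reshape (gh*cs_h, gw*cs_w) into blocks (gh, gw, cs_h, cs_w)."""
    return arr[: gh * cs_h, : gw * cs_w].reshape(gh, cs_h, gw, cs_w).transpose(0, 2, 1, 3)


def _cell_entropies(gray: np.ndarray, tissue: np.ndarray, gh: int, gw: int) -> np.ndarray:
    """Shannon entropy of a 32-bin grayscale histogram over tissue pixels, per cell."""
    cells_g = gray.reshape(gh, gw, -1)
    cells_t = tissue.reshape(gh, gw, -1)
    bins = np.clip((cells_g / 256.0 * _ENTROPY_BINS).astype(np.int64), 0, _ENTROPY_BINS - 1)
    cell_index = np.arange(gh * gw).reshape(gh, gw, 1)
    flat = (cell_index * _ENTROPY_BINS + bins)[cells_t]
    counts = np.bincount(flat, minlength=gh * gw * _ENTROPY_BINS).reshape(gh * gw, _ENTROPY_BINS)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return h.reshape(gh, gw)


def _boundary_counts(tissue_blocks: np.ndarray) -> np.ndarray:
    """Per-cell count of tissue pixels 4-adjacent to background within the cell."""
    t = tissue_blocks
    bg = ~t
    nb = np.zeros_like(t)
    nb[..., 1:, :] |= bg[..., :-1, :]
    nb[..., :-1, :] |= bg[..., 1:, :]
    nb[..., :, 1:] |= bg[..., :, :-1]
    nb[..., :, :-1] |= bg[..., :, 1:]
    return (t & nb).sum(axis=(-2, -1))


def compute_node_features(
    patch: np.ndarray,
    cell_bounds: tuple[int, int, int, int],
    mask: np.ndarray,
) -> np.ndarray:
    """Feature 8-vector for one grid cell (row0, row1, col0, col1).

    Convenience single-cell path; `build_grid_graph` uses the vectorised
    whole-image equivalent and the two agree to float precision.
    """
    r0, r1, c0, c1 = cell_bounds
    fp = patch.astype(np.float64)
    full_gray = fp.mean(axis=2)
    # filter responses use the whole patch so cell borders keep their context
    lap = laplace(full_gray, ksize=3)[r0:r1, c0:c1]
    sob = sobel(full_gray)[r0:r1, c0:c1]
    sub = fp[r0:r1, c0:c1]
    sub_mask = mask[r0:r1, c0:c1]
    gray = full_gray[r0:r1, c0:c1]
    hed = rgb2hed(sub / 255.0)
    sat = rgb2hsv(sub / 255.0)[..., 1]
    bins = np.clip((gray / 256.0 * _ENTROPY_BINS).astype(np.int64), 0, _ENTROPY_BINS - 1)
    tb = bins[sub_mask]
    if tb.size:
        p = np.bincount(tb, minlength=_ENTROPY_BINS) / tb.size
        entropy = float(-np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0).sum())
    else:
        entropy = 0.0
    n_boundary = int(_boundary_counts(sub_mask[None, ...])[0])
    return np.array(
        [
            gray.mean(),
            entropy,
            lap.var(),
            hed[..., 0].mean(),
            hed[..., 1].mean(),
            sat.mean(),
            sob.var(),
            sub_mask.sum() / (1.0 + n_boundary),
        ]
    )


def build_grid_graph(patch: np.ndarray, spec: GridSpec = GridSpec()) -> TissueGraph:
    """Construct the tissue grid graph and its normalized Laplacian.

    Cells are ``floor(H/grid) x floor(W/grid)`` blocks; trailing remainder
    pixels are ignored. Raises :class:`EmptyGraphError` when no cell reaches
    the tissue threshold.
    """
    patch = validate_patch(patch, spec.grid_size)
    H, W = patch.shape[:2]
    g = spec.grid_size
    cs_h, cs_w = H // g, W // g
    gh, gw = g, g

    mask = segment_tissue_mask(patch, spec)
    fp = patch.astype(np.float64)

    gray = fp.mean(axis=2)
    hed = rgb2hed(fp / 255.0)
    sat = rgb2hsv(fp / 255.0)[..., 1]
    lap = laplace(gray, ksize=3)
    sob = sobel(gray)

    gray_b = _block_view(gray, gh, gw, cs_h, cs_w)
    mask_b = _block_view(mask, gh, gw, cs_h, cs_w)
    tissue_frac = mask_b.mean(axis=(-2, -1))
    valid = tissue_frac >= spec.tissue_threshold
    if not valid.any():
        raise EmptyGraphError("no grid cell reaches the tissue threshold")

    feats = np.empty((gh, gw, 8))
    feats[..., 0] = gray_b.mean(axis=(-2, -1))
    feats[..., 1] = _cell_entropies(
        gray_b.reshape(gh, gw, -1), mask_b.reshape(gh, gw, -1), gh, gw
    )
    feats[..., 2] = _block_view(lap, gh, gw, cs_h, cs_w).var(axis=(-2, -1))
    feats[..., 3] = _block_view(hed[..., 0], gh, gw, cs_h, cs_w).mean(axis=(-2, -1))
    feats[..., 4] = _block_view(hed[..., 1], gh, gw, cs_h, cs_w).mean(axis=(-2, -1))
    feats[..., 5] = _block_view(sat, gh, gw, cs_h, cs_w).mean(axis=(-2, -1))
    feats[..., 6] = _block_view(sob, gh, gw, cs_h, cs_w).var(axis=(-2, -1))
    n_tissue = mask_b.sum(axis=(-2, -1))
    n_boundary = _boundary_counts(mask_b.reshape(gh * gw, cs_h, cs_w)).reshape(gh, gw)
    feats[..., 7] = n_tissue / (1.0 + n_boundary)

    rows, cols = np.nonzero(valid)
    node_ids = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    n = len(node_ids)
    positions = np.column_stack(
        [cols * cs_w + cs_w / 2.0, rows * cs_h + cs_h / 2.0]
    ).astype(np.float64)
    X = feats[rows, cols]

    sigma_p = float(spec.sigma_p) if spec.sigma_p != "auto" else float((cs_h + cs_w) / 2.0)
    if spec.sigma_I == "auto":
        sigma_I = float(np.std(X[:, 0]))
        if sigma_I == 0.0:
            sigma_I = 1.0
    else:
        sigma_I = float(spec.sigma_I)

    if spec.use_feature_vector_intensity:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        intensity = (X - mu) / sd
    else:
        intensity = X[:, 0:1]

    ii, jj, ww = [], [], []
    for (r, c), i in node_ids.items():
        for dr, dc in ((0, 1), (1, 0)):
            j = node_ids.get((r + dr, c + dc))
            if j is not None:
                w = edge_weight(
                    positions[i], positions[j], intensity[i], intensity[j], sigma_p, sigma_I
                )
                ii.extend((i, j))
                jj.extend((j, i))
                ww.extend((w, w))
    Wmat = sp.csr_matrix((ww, (ii, jj)), shape=(n, n))
    return TissueGraph(
        node_ids=node_ids,
        positions=positions,
        features=X,
        weights=Wmat,
        laplacian=normalized_laplacian(Wmat),
        grid_shape=(gh, gw),
    )
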