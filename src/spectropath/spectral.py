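"""Spectral descriptors of the tissue-graph Laplacian.

All descriptors are functions of the truncated eigensystem L u_k = lambda_k u_k
of the normalized Laplacian and of the spectral coefficients a_{c,k} = u_k^T x_c
obtained by projecting the 8 node-feature channels onto the eigenbasis:

* heat kernel signature      h_t(i) = sum_k exp(-t lambda_k) u_k(i)^2
* spectral wavelet energy    E_c(t) = sum_k (exp(-t lambda_k) a_{c,k})^2
* Slepian concentration      C_j = (u_j^T M u_j) / (u_j^T u_j)
* band energies over [0, 2], log-log fractal slope, Renyi dimensions D_q,
  lacunarity Var/Mean^2 + 1 over sliding band windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AllZeroEnergyError, ConvergenceFailureError, InsufficientBandsError


@dataclass
class EigenSystem:
    """Truncated ascending eigenpairs of a normalized Laplacian."""

    lambdas: np.ndarray  # (K,), ascending, in [0, 2]
    vectors: np.ndarray  # (N, K), orthonormal columns, sign-fixed

    @property
    def K(self) -> int:
        return self.lambdas.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make the largest-|component| entry of each eigenvector positive.

    Ties broken by the lowest index, so the convention is deterministic and
    permutation-equivariant for simple spectra.
    """
    U = U.copy()
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def eigendecompose(L: sp.spmatrix | np.ndarray, K: int) -> EigenSystem:
    """K smallest eigenpairs of the (symmetric) Laplacian, ascending.

    Uses a shifted Lanczos solve for large sparse problems with a dense
    fallback; raises :class:`ConvergenceFailureError` only when both fail.
    """
    n = L.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds graph size N={n}")
    # dense up to N=1500: comparable speed at these sizes and, unlike the
    # restarted Lanczos solver, bitwise reproducible run to run
    dense_needed = K >= n - 1 or n <= 1500
    if not dense_needed and sp.issparse(L):
        try:
            # sigma-shift avoids stagnation at the lambda=0 eigenspace; the
            # fixed start vector keeps the decomposition deterministic
            v0 = np.full(n, 1.0 / np.sqrt(n))
            lams, U = spla.eigsh(L.tocsc().astype(np.float64), k=K, sigma=-0.01, v0=v0)
        except Exception:
            if n > 4096:
                raise ConvergenceFailureError(f"eigsh failed on N={n}") from None
            dense_needed = True
    else:
        dense_needed = True
    if dense_needed:
        Ld = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=np.float64)
        lams, U = scipy.linalg.eigh(Ld)
        lams, U = lams[:K], U[:, :K]
    order = np.argsort(lams, kind="stable")
    lams, U = lams[order], U[:, order]
    lams = np.clip(lams, 0.0, 2.0)
    return EigenSystem(lambdas=lams, vectors=_fix_signs(U))


def spectral_coefficients(U: np.ndarray, X: np.ndarray) -> np.ndarray:
    """a_{c,k} = u_k^T x_c for each feature channel c; returns (C, K)."""
    U = np.asarray(U, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if U.shape[0] != X.shape[0]:
        raise ValueError(f"node counts differ: U has {U.shape[0]}, X has {X.shape[0]}")
    return X.T @ U


def heat_kernel_signature(
    eig: EigenSystem,
    times: np.ndarray | list[float],
    lambda_cutoff: float | None = 0.02,
) -> np.ndarray:
    """h_t(i) = sum over {k : lambda_k <= cutoff} of exp(-t lambda_k) u_k(i)^2.

    Returns (n_times, N). ``lambda_cutoff=None`` disables the low-pass cut,
    in which case at K=N the t=0 signature is identically 1 (orthonormal rows).
    """
    times = np.asarray(times, dtype=np.float64)
    keep = np.ones(eig.K, dtype=bool) if lambda_cutoff is None else eig.lambdas <= lambda_cutoff
    lam = eig.lambdas[keep]
    U2 = eig.vectors[:, keep] ** 2
    decay = np.exp(-np.outer(times, lam))  # (T, K')
    return decay @ U2.T


def wavelet_energy(
    eig: EigenSystem, coeffs: np.ndarray, times: np.ndarray | list[float]
) -> np.ndarray:
    """E_c(t) = sum_k (exp(-t lambda_k) a_{c,k})^2, shape (C, n_times).

    Squared-norm form, so the energy is nonnegative and non-increasing in t.
    """
    times = np.asarray(times, dtype=np.float64)
    decay2 = np.exp(-2.0 * np.outer(eig.lambdas, times))  # (K, T)
    return (coeffs**2) @ decay2


def slepian_concentration(U: np.ndarray, M: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Rayleigh quotients C_j = (u_j^T M u_j)/(u_j^T u_j) per eigenvector."""
    U = np.asarray(U, dtype=np.float64)
    if M.shape[0] != M.shape[1] or M.shape[0] != U.shape[0]:
        raise ValueError("M must be N x N for N-row U")
    MU = M @ U
    num = np.einsum("ij,ij->j", U, MU)
    den = np.einsum("ij,ij->j", U, U)
    return num / den


def band_energies(
    coeffs: np.ndarray,
    lambdas: np.ndarray,
    B: int = 8,
    per_channel: bool = False,
) -> np.ndarray:
    """Spectral energy per equal-width eigenvalue band on [0, 2].

    Band k (1-based) covers [2(k-1)/B, 2k/B); the last band is closed at 2.
    Pooled mode sums a^2 over channels, giving shape (B,); per-channel mode
    returns (C, B). Raises :class:`AllZeroEnergyError` when total energy is 0.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    idx = np.clip((np.asarray(lambdas) / 2.0 * B).astype(np.int64), 0, B - 1)
    E = np.zeros((coeffs.shape[0], B))
    np.add.at(E.T, idx, (coeffs**2).T)
    if not per_channel:
        E = E.sum(axis=0)
    if E.sum() == 0.0:
        raise AllZeroEnergyError("all spectral bands carry zero energy")
    return E


def band_distribution(E: np.ndarray) -> np.ndarray:
    """Normalize band energies to a probability vector p(k) = E(k)/sum E."""
    E = np.asarray(E, dtype=np.float64)
    total = E.sum()
    if total == 0:
        raise AllZeroEnergyError("cannot normalize zero band energies")
    return E / total


def fractal_slope(E: np.ndarray) -> float:
    """Least-squares slope of log E(k) against log k over positive bands."""
    E = np.asarray(E, dtype=np.float64)
    k = np.arange(1, E.shape[0] + 1)
    pos = E > 0
    if pos.sum() < 2:
        raise InsufficientBandsError("need >= 2 positive-energy bands for a slope")
    x, y = np.log(k[pos]), np.log(E[pos])
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def renyi_dimension(p: np.ndarray, q: float, B: int | None = None) -> float:
    """Generalized dimension D_q = log(sum p^q) / ((q-1) log B).

    At q=1 the limit is D_1 = (sum p log p)/log B. Note the sign: the uniform
    distribution gives D_q = -1 under this normalization (the negative of the
    conventional Renyi dimension), kept as-is for descriptor consistency.
    """
    p = np.asarray(p, dtype=np.float64)
    B = p.shape[0] if B is None else B
    if B < 2:
        raise ValueError("B must be >= 2")
    logB = np.log(B)
    if abs(q - 1.0) < 1e-12:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return float(terms.sum() / logB)
    return float(np.log(np.sum(p**q)) / ((q - 1.0) * logB))


def lacunarity(E: np.ndarray, w: int) -> np.ndarray:
    """Lambda = Var/Mean^2 + 1 over each sliding window of length w.

    Population variance; all-zero windows are defined to have Lambda = 1.
    Returns (B - w + 1,) values, each >= 1.
    """
    E = np.asarray(E, dtype=np.float64)
    B = E.shape[0]
    if not 1 <= w <= B:
        raise ValueError("window length must satisfy 1 <= w <= B")
    n_win = B - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(E, w)
    means = windows.mean(axis=1)
    var = windows.var(axis=1)
    out = np.ones(n_win)
    nz = means != 0
    out[nz] = var[nz] / means[nz] ** 2 + 1.0
    return out


def spectral_embedding(
    eig: EigenSystem,
    coeffs: np.ndarray | None = None,
    K_embed: int = 8,
    scale_by_coefficients: bool = False,
) -> np.ndarray:
    """Per-node point cloud (u_1(i), ..., u_{K_embed}(i)) for the filtration.

    Optionally scales axis k by the channel-pooled coefficient magnitude
    sqrt(sum_c a_{c,k}^2) so high-energy modes dominate pairwise distances.
    """
    if K_embed > eig.K:
        raise ValueError("K_embed exceeds available eigenpairs")
    pts = eig.vectors[:, :K_embed].copy()
    if scale_by_coefficients:
        if coeffs is None:
            raise ValueError("coefficient scaling requested without coefficients")
        scale = np.sqrt((coeffs[:, :K_embed] ** 2).sum(axis=0))
        pts = pts * scale
    return pts
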