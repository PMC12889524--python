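"""Vietoris-Rips persistent homology (H0, H1) of a finite point set.

The filtration assigns every simplex its largest pairwise distance; as the
radius epsilon grows, components merge (H0 deaths) and loops appear and fill
in (H1 births/deaths). H0 is computed with a union-find over edges in
filtration order; H1 by Z2 boundary-matrix reduction of triangle columns
against cycle-creating edges, with the clearing optimization implicit in only
reducing dimension-2 columns. The filtration is truncated at ``eps_max``:
features alive there are reported as essential bars with infinite death.

Zero-persistence pairs (death == birth) are discarded in every dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PersistenceDiagram:
    """Bars (dim, birth, death); death may be ``math.inf`` for essential bars."""

    bars: list[tuple[int, float, float]] = field(default_factory=list)

    def finite_lifetimes(self, dim: int | None = None) -> np.ndarray:
        vals = [
            d - b
            for (h, b, d) in self.bars
            if math.isfinite(d) and (dim is None or h == dim)
        ]
        return np.asarray(vals, dtype=np.float64)

    def in_dim(self, dim: int) -> list[tuple[float, float]]:
        return [(b, d) for (h, b, d) in self.bars if h == dim]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def vietoris_rips_persistence(
    distances: np.ndarray, eps_max: float, max_dim: int = 1
) -> PersistenceDiagram:
    """Persistence diagram of the VR filtration truncated at ``eps_max``.

    ``distances`` must be a symmetric nonnegative matrix with zero diagonal.
    All H0 bars are born at 0; every connected component at eps_max yields one
    essential H0 bar.
    """
    D = np.asarray(distances, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or np.abs(np.diag(D)).max(initial=0.0) > 1e-12:
        raise ValueError("distances must be symmetric with zero diagonal")
    if max_dim not in (0, 1):
        raise ValueError("only homology dimensions 0 and 1 are supported")

    iu, ju = np.triu_indices(n, k=1)
    vals = D[iu, ju]
    keep = vals <= eps_max
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    order = np.lexsort((ju, iu, vals))
    iu, ju, vals = iu[order], ju[order], vals[order]

    bars: list[tuple[int, float, float]] = []
    uf = _UnionFind(n)
    positive_edges: list[int] = []  # indices into the sorted edge list
    for e, (a, b, v) in enumerate(zip(iu, ju, vals)):
        if uf.union(int(a), int(b)):
            if v > 0:
                bars.append((0, 0.0, float(v)))
        else:
            positive_edges.append(e)
    n_components = len({uf.find(i) for i in range(n)})
    bars.extend((0, 0.0, math.inf) for _ in range(n_components))

    if max_dim >= 1 and n >= 3:
        bars.extend(_h1_bars(n, D, eps_max, iu, ju, vals, positive_edges))
    return PersistenceDiagram(bars=bars)


def _h1_bars(n, D, eps_max, iu, ju, vals, positive_edges):
    # edge (i, j) -> row index in filtration order
    edge_row = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(iu, ju))}
    pos_set = set(positive_edges)

    tri: list[tuple[float, int, int, int]] = []
    for i in range(n - 2):
        row = D[i]
        nbrs = np.nonzero(row[i + 1 :] <= eps_max)[0] + i + 1
        for a_idx in range(len(nbrs) - 1):
            j = int(nbrs[a_idx])
            for k in nbrs[a_idx + 1 :]:
                k = int(k)
                djk = D[j, k]
                if djk <= eps_max:
                    f = max(row[j], row[k], djk)
                    tri.append((float(f), i, j, k))
    tri.sort()

    low_to_col: dict[int, tuple[int, ...]] = {}
    low_to_val: dict[int, float] = {}
    bars: list[tuple[int, float, float]] = []
    for f, i, j, k in tri:
        col = {edge_row[(i, j)], edge_row[(i, k)], edge_row[(j, k)]}
        low = max(col)
        while low in low_to_col:
            col ^= set(low_to_col[low])
            if not col:
                break
            low = max(col)
        if col:
            low_to_col[low] = tuple(col)
            low_to_val[low] = f
    for e in positive_edges:
        birth = float(vals[e])
        if e in low_to_val:
            death = low_to_val[e]
            if death > birth:
                bars.append((1, birth, death))
        else:
            bars.append((1, birth, math.inf))
    return bars


def persistence_entropy(diagram: PersistenceDiagram) -> tuple[float, float]:
    """Total finite lifetime and Shannon entropy of normalized lifetimes.

    Essential (infinite) bars are excluded; an empty diagram returns (0, 0).
    """
    ell = diagram.finite_lifetimes()
    total = float(ell.sum())
    if total == 0.0 or ell.size == 0:
        return 0.0, 0.0
    p = ell / total
    H = float(-(p * np.log(p)).sum())
    return total, H


def subsample_points(points: np.ndarray, max_points: int) -> np.ndarray:
    """Deterministic, permutation-invariant subsample of a point cloud.

    Points are sorted lexicographically by coordinates and taken at an even
    stride, so any relabeling of the input rows yields the same subset.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    if n <= max_points:
        return pts
    order = np.lexsort(pts.T[::-1])  # primary key: first coordinate
    idx = np.linspace(0, n - 1, max_points).round().astype(int)
    return pts[order][idx]
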