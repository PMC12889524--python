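"""Independent brute-force oracles used only by the tests.

These re-derive quantities by the most naive correct route available —
explicit boundary-matrix reduction over the full simplicial complex for
Vietoris-Rips persistence, exhaustive pair counting for AUC — so the
package implementations are checked against something that shares none of
their code paths.
"""

import math
from itertools import combinations

import numpy as np


def brute_force_vr_diagram(points_or_distances, eps_max, max_dim=1):
    """VR persistence by full boundary-matrix reduction (<= ~8 points).

    Enumerates every simplex up to dimension max_dim + 1 with filtration
    value = max pairwise distance, sorts by (value, dim, lex), reduces the
    global boundary matrix over Z2 with the standard column algorithm, and
    reads bars off the pivot pairing. Zero-persistence pairs are dropped;
    unpaired creators of dim <= max_dim become essential bars.
    """
    D = np.asarray(points_or_distances, dtype=np.float64)
    if D.ndim == 2 and D.shape[0] != D.shape[1]:
        diff = D[:, None, :] - D[None, :, :]
        D = np.sqrt((diff**2).sum(-1))
    n = D.shape[0]

    simplices = []
    for d in range(0, max_dim + 2):
        for verts in combinations(range(n), d + 1):
            if d == 0:
                f = 0.0
            else:
                f = max(D[a][b] for a, b in combinations(verts, 2))
            if f <= eps_max:
                simplices.append((f, d, verts))
    simplices.sort()
    index = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for f, d, verts in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index[face] for face in combinations(verts, d)})

    low_of = {}
    pair = {}
    for j, col in enumerate(columns):
        col = set(col)
        while col:
            low = max(col)
            if low not in low_of:
                low_of[low] = j
                pair[low] = j
                break
            col ^= columns[low_of[low]]
        columns[j] = col

    creators = {j for j, col in enumerate(columns) if not col}
    bars = []
    for birth_idx, death_idx in pair.items():
        if birth_idx not in creators:
            continue
        fb, db_dim, _ = simplices[birth_idx]
        fd, _, _ = simplices[death_idx]
        if fd > fb and db_dim <= max_dim:
            bars.append((db_dim, fb, fd))
    for j in creators - set(pair.keys()):
        f, d, _ = simplices[j]
        if d <= max_dim:
            bars.append((d, f, math.inf))
    return sorted(bars)


def canonical_bars(diagram_or_bars):
    bars = getattr(diagram_or_bars, "bars", diagram_or_bars)
    return sorted((d, round(b, 9), round(dd, 9) if math.isfinite(dd) else math.inf)
                  for d, b, dd in bars)


def brute_force_auc(y_true, scores):
    """AUC by exhaustive positive/negative pair comparison, ties half."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
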