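"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementation paths: the Sobel
oracle builds dense 3x3x3 kernels and convolves them with explicit loops;
the watershed oracle computes the per-voxel optimum (minimax path cost,
label) by Bellman-Ford relaxation to a fixed point.
"""

from __future__ import annotations

import itertools

import numpy as np

_SMOOTH = np.array([1.0, 2.0, 1.0])
_DERIV = np.array([-1.0, 0.0, 1.0])


def sobel_kernel(axis: int) -> np.ndarray:
    """Dense 3x3x3 Sobel kernel for the derivative along ``axis``."""
    parts = [_SMOOTH, _SMOOTH, _SMOOTH]
    parts[axis] = _DERIV
    return np.einsum("i,j,k->ijk", parts[0], parts[1], parts[2])


def sobel_magnitude_dense(vol: np.ndarray) -> np.ndarray:
    """Gradient magnitude by direct correlation with edge-replicated borders."""
    vol = np.asarray(vol, dtype=np.float64)
    padded = np.pad(vol, 1, mode="edge")
    out = np.zeros_like(vol)
    for axis in range(3):
        k = sobel_kernel(axis)
        g = np.zeros_like(vol)
        for i, j, l in itertools.product(range(3), repeat=3):
            # correlation: kernel index (i,j,l) multiplies the neighbour at
            # offset (i-1, j-1, l-1); ndimage.sobel flips the derivative
            # stencil (convolution), so flip here to match the same operator
            g += k[2 - i, 2 - j, 2 - l] * padded[
                i : i + vol.shape[0], j : j + vol.shape[1], l : l + vol.shape[2]
            ]
        out += g * g
    return np.sqrt(out)


def _neighbors(idx, shape):
    for axis in range(3):
        for step in (-1, 1):
            nb = list(idx)
            nb[axis] += step
            if 0 <= nb[axis] < shape[axis]:
                yield tuple(nb)


def minimax_labels(edges: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Brute-force Dijkstra-style minimax assignment (no heap, O(n^2)).

    Repeatedly scans ALL frontier candidates and assigns the global
    lexicographic minimum of (path cost, label, linear index), where the
    path cost of a voxel is max(cost of the assigned neighbour it is entered
    from, its own edge value).  Seeds start at their own edge value."""
    edges = np.asarray(edges, dtype=float)
    markers = np.asarray(markers)
    shape = edges.shape
    out = np.array(markers, dtype=np.int64)
    cost = np.full(shape, np.inf)
    assigned = markers != 0
    for idx in np.ndindex(shape):
        if assigned[idx]:
            cost[idx] = edges[idx]
    n_left = int((~assigned).sum())
    for _ in range(n_left):
        best = None
        for idx in np.ndindex(shape):  # scan every voxel, every round
            if not assigned[idx]:
                continue
            for nb in _neighbors(idx, shape):
                if assigned[nb]:
                    continue
                cand = (
                    max(cost[idx], edges[nb]),
                    int(out[idx]),
                    int(np.ravel_multi_index(nb, shape)),
                )
                if best is None or cand < best:
                    best = cand
        if best is None:  # disconnected (cannot happen on a full grid)
            break
        c, lbl, lin = best
        nb = np.unravel_index(lin, shape)
        assigned[nb] = True
        cost[nb] = c
        out[nb] = lbl
    return out


def per_label_minimax_costs(edges: np.ndarray, markers: np.ndarray) -> dict[int, np.ndarray]:
    """Unconstrained minimax path cost from each label's seeds to every
    voxel, by value-only relaxation (independent of any flooding order)."""
    edges = np.asarray(edges, dtype=float)
    markers = np.asarray(markers)
    shape = edges.shape
    costs = {}
    for lbl in sorted(set(np.unique(markers)) - {0}):
        c = np.full(shape, np.inf)
        c[markers == lbl] = edges[markers == lbl]
        changed = True
        while changed:
            changed = False
            for idx in np.ndindex(shape):
                for nb in _neighbors(idx, shape):
                    cand = max(c[nb], edges[idx])
                    if cand < c[idx]:
                        c[idx] = cand
                        changed = True
        costs[int(lbl)] = c
    return costs


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom
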