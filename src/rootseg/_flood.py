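"""Numba-accelerated seeded minimax priority flood (watershed core).

Every voxel is assigned the label of the seed that reaches it along the
path whose maximum gradient value is smallest (6-connectivity).  Ties are
broken deterministically: lower path cost first, then lower label id, then
lexicographic (linear) voxel order — the heap orders entries by the triple
(cost, label, linear index).

Seed voxels keep their labels.  Only seed voxels on the boundary of their
marker region are enqueued: an interior seed can never offer a cheaper
minimax path to an unlabeled voxel than the boundary seed it would have to
pass through, so the assignment is unchanged.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - numba is an ordinary dependency
    from numba import njit
except Exception:  # pragma: no cover - plain-Python fallback

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, inline="always")
def _less(c1, l1, i1, c2, l2, i2):
    if c1 != c2:
        return c1 < c2
    if l1 != l2:
        return l1 < l2
    return i1 < i2


@njit(cache=True)
def _sift_up(hc, hl, hi, k):
    while k > 0:
        p = (k - 1) // 2
        if _less(hc[k], hl[k], hi[k], hc[p], hl[p], hi[p]):
            hc[k], hc[p] = hc[p], hc[k]
            hl[k], hl[p] = hl[p], hl[k]
            hi[k], hi[p] = hi[p], hi[k]
            k = p
        else:
            break


@njit(cache=True)
def _sift_down(hc, hl, hi, n):
    k = 0
    while True:
        a, b = 2 * k + 1, 2 * k + 2
        m = k
        if a < n and _less(hc[a], hl[a], hi[a], hc[m], hl[m], hi[m]):
            m = a
        if b < n and _less(hc[b], hl[b], hi[b], hc[m], hl[m], hi[m]):
            m = b
        if m == k:
            break
        hc[k], hc[m] = hc[m], hc[k]
        hl[k], hl[m] = hl[m], hl[k]
        hi[k], hi[m] = hi[m], hi[k]
        k = m


@njit(cache=True)
def _flood_kernel(edges, seed_queue, seed_costs, seed_labels, out, nx, ny, nz):
    ntot = nx * ny * nz
    cap = max(4 * len(seed_queue) + 64, 1 << 16)
    hc = np.empty(cap, dtype=np.float64)
    hl = np.empty(cap, dtype=np.int64)
    hi = np.empty(cap, dtype=np.int64)
    n = 0
    for s in range(len(seed_queue)):
        hc[n] = seed_costs[s]
        hl[n] = seed_labels[s]
        hi[n] = seed_queue[s]
        _sift_up(hc, hl, hi, n)
        n += 1
    syz = ny * nz
    done = np.zeros(ntot, dtype=np.uint8)
    while n > 0:
        c, l, i = hc[0], hl[0], hi[0]
        n -= 1
        hc[0], hl[0], hi[0] = hc[n], hl[n], hi[n]
        _sift_down(hc, hl, hi, n)
        if done[i]:
            continue
        done[i] = 1
        if out[i] == 0:
            out[i] = l
        else:
            l = out[i]
        ix = i // syz
        iy = (i % syz) // nz
        iz = i % nz
        for d in range(6):
            if d == 0:
                jx, jy, jz = ix - 1, iy, iz
            elif d == 1:
                jx, jy, jz = ix + 1, iy, iz
            elif d == 2:
                jx, jy, jz = ix, iy - 1, iz
            elif d == 3:
                jx, jy, jz = ix, iy + 1, iz
            elif d == 4:
                jx, jy, jz = ix, iy, iz - 1
            else:
                jx, jy, jz = ix, iy, iz + 1
            if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                continue
            j = jx * syz + jy * nz + jz
            if done[j] or out[j] != 0:
                continue
            cj = edges[j]
            if cj < c:
                cj = c
            if n >= cap:  # grow heap
                newcap = cap * 2
                nhc = np.empty(newcap, dtype=np.float64)
                nhl = np.empty(newcap, dtype=np.int64)
                nhi = np.empty(newcap, dtype=np.int64)
                nhc[:n] = hc[:n]
                nhl[:n] = hl[:n]
                nhi[:n] = hi[:n]
                hc, hl, hi, cap = nhc, nhl, nhi, newcap
            hc[n] = cj
            hl[n] = l
            hi[n] = j
            _sift_up(hc, hl, hi, n)
            n += 1


def flood(edges: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Run the seeded minimax flood; returns the full label assignment."""
    edges = np.ascontiguousarray(edges, dtype=np.float64)
    markers = np.ascontiguousarray(markers, dtype=np.int64)
    nx, ny, nz = edges.shape
    out = markers.copy()

    seeded = markers != 0
    # boundary seeds: seed voxels with at least one unseeded 6-neighbour
    boundary = np.zeros_like(seeded)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(~seeded, shift, axis=axis)
            # roll wraps around; mask the wrapped face
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = False
            boundary |= seeded & rolled
    # faces of the grid: a seed on the volume border with no interior
    # unseeded neighbour can still be a boundary in degenerate cases; the
    # all-seeded case needs no flood at all.
    idx = np.flatnonzero(boundary.ravel())
    flat_e = edges.ravel()
    flat_m = markers.ravel()
    if idx.size:
        _flood_kernel(flat_e, idx, flat_e[idx], flat_m[idx], out.ravel(), nx, ny, nz)
    return out
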