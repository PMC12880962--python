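"""Compiled inner loops: chamfer raster scans and topology-preserving removal.

The 3x3x3 neighbourhood combinatorics (26-adjacency for foreground,
6-adjacency for background) are precomputed as flat CSR-style tables at
import time; the per-voxel work runs under numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- neighbourhood tables --------------------------------------------------

def _build_offsets():
    offs = []
    weights = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                n = abs(dx) + abs(dy) + abs(dz)
                offs.append((dx, dy, dz))
                weights.append((3.0, 4.0, 5.0)[n - 1])
    return np.array(offs, dtype=np.int64), np.array(weights, dtype=np.float64)


OFFSETS26, CHAMFER_W = _build_offsets()

# forward = offsets lexicographically before (0,0,0) in (x, y, z) scan order
_fwd = [
    i
    for i, (dx, dy, dz) in enumerate(OFFSETS26)
    if (dx < 0) or (dx == 0 and dy < 0) or (dx == 0 and dy == 0 and dz < 0)
]
FWD_OFFSETS = OFFSETS26[_fwd]
FWD_W = CHAMFER_W[_fwd]
BWD_OFFSETS = -FWD_OFFSETS
BWD_W = FWD_W.copy()


def _patch_index(dx, dy, dz):
    return (dx + 1) * 9 + (dy + 1) * 3 + (dz + 1)


def _build_patch_tables():
    """Adjacency tables over the 27 positions of a 3x3x3 patch."""
    coords = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    center = _patch_index(0, 0, 0)

    def csr(adjacent):
        starts = np.zeros(28, dtype=np.int64)
        flat = []
        for p, a in enumerate(coords):
            nbrs = [
                q
                for q, b in enumerate(coords)
                if q != p and q != center and p != center and adjacent(a, b)
            ]
            starts[p + 1] = starts[p] + len(nbrs)
            flat.extend(nbrs)
        return starts, np.array(flat, dtype=np.int64)

    def adj26(a, b):
        return max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) == 1

    def adj6(a, b):
        return abs(a[0] - b[0]) + abs(a[1] - b[1]) + abs(a[2] - b[2]) == 1

    s26, f26 = csr(adj26)
    s6, f6 = csr(adj6)
    in_n18 = np.array(
        [1 if (sum(map(abs, c)) in (1, 2)) else 0 for c in coords], dtype=np.uint8
    )
    face = np.array([1 if sum(map(abs, c)) == 1 else 0 for c in coords], dtype=np.uint8)
    return s26, f26, s6, f6, in_n18, face


ADJ26_START, ADJ26_FLAT, ADJ6_START, ADJ6_FLAT, IN_N18, IS_FACE = _build_patch_tables()


# -- chamfer distance transform -------------------------------------------

@njit(cache=True)
def chamfer_two_pass(fg, offs_f, w_f, offs_b, w_b):
    """Two raster scans of the 3-4-5 chamfer transform over a boolean grid."""
    nx, ny, nz = fg.shape
    INF = 1e30
    dist = np.empty((nx, ny, nz), dtype=np.float64)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                dist[i, j, k] = INF if fg[i, j, k] else 0.0
    # forward
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not fg[i, j, k]:
                    continue
                d = dist[i, j, k]
                for m in range(offs_f.shape[0]):
                    ii = i + offs_f[m, 0]
                    jj = j + offs_f[m, 1]
                    kk = k + offs_f[m, 2]
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        c = dist[ii, jj, kk] + w_f[m]
                        if c < d:
                            d = c
                dist[i, j, k] = d
    # backward
    for i in range(nx - 1, -1, -1):
        for j in range(ny - 1, -1, -1):
            for k in range(nz - 1, -1, -1):
                if not fg[i, j, k]:
                    continue
                d = dist[i, j, k]
                for m in range(offs_b.shape[0]):
                    ii = i + offs_b[m, 0]
                    jj = j + offs_b[m, 1]
                    kk = k + offs_b[m, 2]
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        c = dist[ii, jj, kk] + w_b[m]
                        if c < d:
                            d = c
                dist[i, j, k] = d
    return dist


# -- simple-point test -----------------------------------------------------

@njit(cache=True)
def _is_simple(patch, adj26_start, adj26_flat, adj6_start, adj6_flat, in_n18, is_face):
    """(26, 6) simple-point test on a flat 27-voxel patch (centre index 13).

    The centre is removable iff the foreground in its 26-neighbourhood forms
    exactly one 26-connected component, and the background within the
    18-neighbourhood forms exactly one 6-connected component that touches a
    face neighbour.
    """
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)

    # exactly one 26-component of foreground among the 26 neighbours
    n_fg = 0
    first_fg = -1
    for p in range(27):
        if p != 13 and patch[p] == 1:
            n_fg += 1
            if first_fg < 0:
                first_fg = p
    if n_fg == 0:
        return False
    top = 0
    stack[top] = first_fg
    top += 1
    visited[first_fg] = 1
    seen = 1
    while top > 0:
        top -= 1
        p = stack[top]
        for q_i in range(adj26_start[p], adj26_start[p + 1]):
            q = adj26_flat[q_i]
            if patch[q] == 1 and visited[q] == 0:
                visited[q] = 1
                seen += 1
                stack[top] = q
                top += 1
    if seen != n_fg:
        return False

    # exactly one 6-component of background in N18 adjacent to the centre
    for p in range(27):
        visited[p] = 0
    n_components = 0
    for f in range(27):
        if is_face[f] == 0 or patch[f] == 1 or visited[f] == 1:
            continue
        n_components += 1
        if n_components > 1:
            return False
        top = 0
        stack[top] = f
        top += 1
        visited[f] = 1
        while top > 0:
            top -= 1
            p = stack[top]
            for q_i in range(adj6_start[p], adj6_start[p + 1]):
                q = adj6_flat[q_i]
                if in_n18[q] == 1 and patch[q] == 0 and visited[q] == 0:
                    visited[q] = 1
                    stack[top] = q
                    top += 1
    return n_components == 1


@njit(cache=True)
def thin_in_distance_order(
    fg,
    order_i,
    order_j,
    order_k,
    order_d,
    anchored,
    protect_ends,
    adj26_start,
    adj26_flat,
    adj6_start,
    adj6_flat,
    in_n18,
    is_face,
    offsets26,
):
    """Remove simple, non-anchored, non-line-end voxels in distance order.

    ``fg`` must be padded by one background voxel on every side; the order
    arrays hold padded coordinates sorted by (distance, lexicographic index)
    with ``order_d`` the corresponding chamfer distances.  ``anchored`` marks
    voxels that must survive (centres of maximal balls in the first
    skeletonization pass).  Each distance layer is swept repeatedly until
    stable before the next layer starts, so removal never races ahead of the
    distance ordering; the whole schedule repeats until no voxel changes.
    Every individual removal preserves (26, 6) digital topology, so
    connectivity of foreground and background is invariant throughout.
    """
    patch = np.empty(27, dtype=np.uint8)
    n = order_i.shape[0]
    any_changed = True
    while any_changed:
        any_changed = False
        start = 0
        while start < n:
            end = start
            while end < n and order_d[end] == order_d[start]:
                end += 1
            layer_changed = True
            while layer_changed:
                layer_changed = False
                for t in range(start, end):
                    i = order_i[t]
                    j = order_j[t]
                    k = order_k[t]
                    if not fg[i, j, k] or anchored[i, j, k]:
                        continue
                    if protect_ends:
                        # line-end protection: keep voxels with <= 1 fg neighbour
                        cnt = 0
                        for m in range(offsets26.shape[0]):
                            if fg[
                                i + offsets26[m, 0],
                                j + offsets26[m, 1],
                                k + offsets26[m, 2],
                            ]:
                                cnt += 1
                        if cnt <= 1:
                            continue
                    p = 0
                    for dx in range(-1, 2):
                        for dy in range(-1, 2):
                            for dz in range(-1, 2):
                                patch[p] = 1 if fg[i + dx, j + dy, k + dz] else 0
                                p += 1
                    if _is_simple(
                        patch, adj26_start, adj26_flat, adj6_start, adj6_flat, in_n18, is_face
                    ):
                        fg[i, j, k] = False
                        layer_changed = True
                        any_changed = True
            start = end
    return fg
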