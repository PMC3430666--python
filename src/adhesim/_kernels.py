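"""Hot inner loops, JIT-compiled when numba is available.

Pure-numpy/scipy fallbacks keep the package functional without numba.
Trajectories remain deterministic for a fixed seed in either case, but
the neighbour-pair enumeration order (and hence the random-stream
consumption) can differ between the two backends.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def relax_rings(ring, centroid, cosn, sinn, r, tol, alpha, max_iter):
    """Shape-matching relaxation of every ring toward the regular
    decagon of radius ``r`` about its centroid.

    Each sweep finds the rotation best aligning the nominal decagon
    with the current ring (2D Procrustes) and moves every body a
    fraction ``alpha`` toward its rotated nominal position, preserving
    angular order by construction.  Returns True once the largest
    radial error is within ``tol``.
    """
    n, m = ring.shape[0], ring.shape[1]
    converged = False
    for _ in range(max_iter):
        maxerr = 0.0
        for i in range(n):
            # translational component: centroid relaxes toward the
            # centre of mass of all 11 bodies, so forces on ring bodies
            # (hooks, collisions) drag the whole cell
            mx = centroid[i, 0]
            my = centroid[i, 1]
            for j in range(m):
                mx += ring[i, j, 0]
                my += ring[i, j, 1]
            mx /= m + 1.0
            my /= m + 1.0
            centroid[i, 0] += alpha * (mx - centroid[i, 0])
            centroid[i, 1] += alpha * (my - centroid[i, 1])
            cx, cy = centroid[i, 0], centroid[i, 1]
            s = 0.0
            c = 0.0
            for j in range(m):
                px = ring[i, j, 0] - cx
                py = ring[i, j, 1] - cy
                c += cosn[j] * px + sinn[j] * py
                s += cosn[j] * py - sinn[j] * px
            norm = math.sqrt(s * s + c * c)
            if norm < 1e-12:
                ct, st = 1.0, 0.0
            else:
                ct, st = c / norm, s / norm
            for j in range(m):
                tx = cx + r * (ct * cosn[j] - st * sinn[j])
                ty = cy + r * (st * cosn[j] + ct * sinn[j])
                ring[i, j, 0] += alpha * (tx - ring[i, j, 0])
                ring[i, j, 1] += alpha * (ty - ring[i, j, 1])
                dx = ring[i, j, 0] - cx
                dy = ring[i, j, 1] - cy
                err = abs(math.sqrt(dx * dx + dy * dy) - r)
                if err > maxerr:
                    maxerr = err
        if maxerr <= tol:
            converged = True
            break
    return converged


@njit(cache=True)
def _neighbor_pairs_impl(pos, cutoff, cap):
    """Cell-list neighbour search: all index pairs (i < j) closer than
    ``cutoff``.  Returns (pairs, count); count = -1 signals the ``cap``
    buffer was too small and the caller must retry with a larger one."""
    n = pos.shape[0]
    out = np.empty((cap, 2), dtype=np.int64)
    if n < 2:
        return out, 0
    xmin = pos[0, 0]
    ymin = pos[0, 1]
    xmax = xmin
    ymax = ymin
    for i in range(n):
        x, y = pos[i, 0], pos[i, 1]
        if x < xmin:
            xmin = x
        elif x > xmax:
            xmax = x
        if y < ymin:
            ymin = y
        elif y > ymax:
            ymax = y
    nx = int((xmax - xmin) / cutoff) + 1
    ny = int((ymax - ymin) / cutoff) + 1
    ncell = nx * ny
    cell = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / cutoff)
        cy = int((pos[i, 1] - ymin) / cutoff)
        c = cx * ny + cy
        cell[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    # counting sort: bucket[start[c]:start[c+1]] lists points of cell c
    fill = counts[:-1].copy()
    bucket = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = cell[i]
        bucket[fill[c]] = i
        fill[c] += 1
    c2 = cutoff * cutoff
    count = 0
    for i in range(n):
        ci = cell[i]
        cx = ci // ny
        cy = ci - cx * ny
        for dx in range(-1, 2):
            ncx = cx + dx
            if ncx < 0 or ncx >= nx:
                continue
            for dy in range(-1, 2):
                ncy = cy + dy
                if ncy < 0 or ncy >= ny:
                    continue
                target = ncx * ny + ncy
                for m in range(counts[target], counts[target + 1]):
                    j = bucket[m]
                    if j <= i:
                        continue
                    ddx = pos[i, 0] - pos[j, 0]
                    ddy = pos[i, 1] - pos[j, 1]
                    if ddx * ddx + ddy * ddy < c2:
                        if count >= cap:
                            return out, -1
                        out[count, 0] = i
                        out[count, 1] = j
                        count += 1
    return out, count


def neighbor_pairs(pos, cutoff):
    """All point-index pairs closer than ``cutoff`` as an (m, 2) array
    (i < j); order is deterministic for fixed input."""
    cap = max(16 * len(pos), 1024)
    while True:
        out, count = _neighbor_pairs_impl(
            np.ascontiguousarray(pos, dtype=np.float64), float(cutoff), cap)
        if count >= 0:
            return out[:count]
        cap *= 4


@njit(cache=True)
def greedy_match(order, pa, pb, free):
    """Grant candidate pairs in the given priority order, skipping any
    pair with an already-taken endpoint; returns the accepted mask."""
    take = np.zeros(len(pa), dtype=np.bool_)
    for k in range(len(order)):
        idx = order[k]
        a, b = pa[idx], pb[idx]
        if free[a] and free[b]:
            free[a] = False
            free[b] = False
            take[idx] = True
    return take


if not HAVE_NUMBA:  # pragma: no cover - numpy/scipy fallbacks
    from scipy.spatial import cKDTree

    def neighbor_pairs(pos, cutoff):  # noqa: F811
        return cKDTree(pos).query_pairs(cutoff, output_type="ndarray")

    def relax_rings(ring, centroid, cosn, sinn, r, tol, alpha,  # noqa: F811
                    max_iter):
        q = np.column_stack([cosn, sinn])
        m = ring.shape[1]
        for _ in range(max_iter):
            com = (ring.sum(1) + centroid) / (m + 1.0)
            centroid += alpha * (com - centroid)
            p = ring - centroid[:, None, :]
            c = np.einsum("jk,ijk->i", q, p)
            s = cosn[None, :] * p[:, :, 1] - sinn[None, :] * p[:, :, 0]
            s = s.sum(1)
            norm = np.sqrt(s * s + c * c)
            ct = np.where(norm > 1e-12, c / np.maximum(norm, 1e-12), 1.0)
            st = np.where(norm > 1e-12, s / np.maximum(norm, 1e-12), 0.0)
            tx = r * (ct[:, None] * cosn[None, :] - st[:, None] * sinn[None, :])
            ty = r * (st[:, None] * cosn[None, :] + ct[:, None] * sinn[None, :])
            target = np.stack([tx, ty], axis=-1) + centroid[:, None, :]
            ring += alpha * (target - ring)
            vec = ring - centroid[:, None, :]
            err = np.abs(np.sqrt((vec * vec).sum(-1)) - r).max()
            if err <= tol:
                return True
        return False

    def greedy_match(order, pa, pb, free):  # noqa: F811
        take = np.zeros(len(pa), dtype=bool)
        for idx in order:
            a, b = pa[idx], pb[idx]
            if free[a] and free[b]:
                free[a] = False
                free[b] = False
                take[idx] = True
        return take
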