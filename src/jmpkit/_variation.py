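"""Numba kernel for the per-vertex surface-variation statistic.

For every vertex the statistic is the volume of the smallest cylinder,
aligned with the vertex normal, that contains the vertex's graph
n-neighborhood: height = extent of the neighbors' projections onto the
normal axis, radius = largest in-plane distance from the axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def variation_kernel(indptr, indices, verts, normals, n_rings):  # pragma: no cover - jit
    nv = verts.shape[0]
    out = np.zeros(nv, dtype=np.float64)
    stamp = np.full(nv, -1, dtype=np.int64)
    queue = np.empty(nv, dtype=np.int64)
    depth = np.empty(nv, dtype=np.int64)
    for v in range(nv):
        px, py, pz = verts[v, 0], verts[v, 1], verts[v, 2]
        ax, ay, az = normals[v, 0], normals[v, 1], normals[v, 2]
        head = 0
        tail = 1
        queue[0] = v
        depth[0] = 0
        stamp[v] = v
        hmin = 0.0
        hmax = 0.0
        r2max = 0.0
        while head < tail:
            u = queue[head]
            d = depth[head]
            head += 1
            dx = verts[u, 0] - px
            dy = verts[u, 1] - py
            dz = verts[u, 2] - pz
            h = dx * ax + dy * ay + dz * az
            r2 = dx * dx + dy * dy + dz * dz - h * h
            if h < hmin:
                hmin = h
            if h > hmax:
                hmax = h
            if r2 > r2max:
                r2max = r2
            if d < n_rings:
                for k in range(indptr[u], indptr[u + 1]):
                    w = indices[k]
                    if stamp[w] != v:
                        stamp[w] = v
                        queue[tail] = w
                        depth[tail] = d + 1
                        tail += 1
        out[v] = np.pi * r2max * (hmax - hmin)
    return out
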