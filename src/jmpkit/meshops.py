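"""Shared triangle-mesh operations: adjacency, smoothing, label morphology,
boundary handling and capping.

All meshes are :class:`trimesh.Trimesh` objects whose vertices are physical
coordinates in micrometres, axis order ``(z, y, x)``.  Neighborhoods are
graph neighborhoods on mesh edges ("1-neighborhood" = vertices sharing an
edge), which is the natural discrete analogue used for mean smoothing and
for morphology on vertex label sets.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import trimesh

from .containers import ParameterError

__all__ = [
    "vertex_adjacency",
    "boundary_vertex_mask",
    "smooth_mesh",
    "dilate_labels",
    "erode_labels",
    "open_labels",
    "close_labels",
    "fill_label_holes",
    "boundary_loops",
    "cap_submesh",
    "make_grid_plane_mesh",
    "make_grid_disk_mesh",
]


def vertex_adjacency(mesh: trimesh.Trimesh) -> sp.csr_matrix:
    """Boolean vertex-vertex adjacency (1-ring) as CSR, without self loops."""
    e = mesh.edges_unique
    n = len(mesh.vertices)
    data = np.ones(len(e), dtype=bool)
    a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
    a = (a + a.T).tocsr()
    a.data[:] = True
    return a


def boundary_vertex_mask(mesh: trimesh.Trimesh) -> np.ndarray:
    """True for vertices on an open boundary (incident to a boundary edge)."""
    n = len(mesh.vertices)
    mask = np.zeros(n, dtype=bool)
    edges = _boundary_edges(mesh)
    if len(edges):
        mask[np.unique(edges)] = True
    return mask


def _boundary_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    """Directed edges that appear in exactly one face, orientation preserved."""
    edges = mesh.edges  # directed, one triple per face
    order = trimesh.grouping.group_rows(np.sort(edges, axis=1), require_count=1)
    return edges[order]


def smooth_mesh(mesh: trimesh.Trimesh, iterations: int = 4) -> trimesh.Trimesh:
    """Mean smoothing: each vertex becomes the mean of itself and its 1-ring.

    Topology is untouched; only vertex positions move.  ``iterations=0``
    returns an identical copy.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    adj = vertex_adjacency(mesh).astype(np.float64)
    n = adj.shape[0]
    op = adj + sp.eye(n, format="csr")
    inv_deg = 1.0 / np.asarray(op.sum(axis=1)).ravel()
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = (op @ v) * inv_deg[:, None]
    return trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# morphology on vertex label sets
# ---------------------------------------------------------------------------

def dilate_labels(adj: sp.csr_matrix, labels: np.ndarray, rings: int = 1) -> np.ndarray:
    """Grow the labeled set by ``rings`` graph rings."""
    out = labels.copy()
    for _ in range(rings):
        out = out | (adj @ out)
    return out


def erode_labels(adj: sp.csr_matrix, labels: np.ndarray, rings: int = 1) -> np.ndarray:
    """Shrink the labeled set: complement-dilate-complement."""
    return ~dilate_labels(adj, ~labels, rings)


def open_labels(adj: sp.csr_matrix, labels: np.ndarray, rings: int = 1) -> np.ndarray:
    return dilate_labels(adj, erode_labels(adj, labels, rings), rings)


def close_labels(adj: sp.csr_matrix, labels: np.ndarray, rings: int = 5) -> np.ndarray:
    return erode_labels(adj, dilate_labels(adj, labels, rings), rings)


def fill_label_holes(adj: sp.csr_matrix, labels: np.ndarray,
                     boundary: np.ndarray) -> np.ndarray:
    """Label unlabeled patches fully enclosed by labeled vertices.

    A "hole" is a connected component of unlabeled vertices that does not
    touch the mesh boundary.  On a closed mesh (no boundary) the largest
    unlabeled component is treated as the outside and kept unlabeled.
    """
    unl = ~labels
    if not unl.any():
        return labels.copy()
    sub = adj[unl][:, unl]
    n_comp, comp = sp.csgraph.connected_components(sub, directed=False)
    comp_full = np.full(labels.shape, -1)
    comp_full[unl] = comp
    out = labels.copy()
    if boundary.any():
        touches = np.zeros(n_comp, dtype=bool)
        touched = comp_full[unl & boundary]
        touches[np.unique(touched)] = True
    else:
        sizes = np.bincount(comp, minlength=n_comp)
        touches = np.zeros(n_comp, dtype=bool)
        touches[np.argmax(sizes)] = True
    for c in range(n_comp):
        if not touches[c]:
            out[comp_full == c] = True
    return out


# ---------------------------------------------------------------------------
# boundary loops and capping
# ---------------------------------------------------------------------------

def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of each open boundary, following face orientation."""
    edges = _boundary_edges(mesh)
    if len(edges) == 0:
        return []
    nxt = dict(map(tuple, edges))
    loops = []
    seen: set[int] = set()
    for start in nxt:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in seen:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(np.asarray(loop))
    return loops


def cap_submesh(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, float]:
    """Close every open boundary loop with a fan to the loop centroid.

    Returns the capped mesh and the total area of the cap triangles (the
    protrusion's base area).  The input orientation is preserved so the
    divergence-theorem volume of the result is meaningful.
    """
    loops = boundary_loops(mesh)
    if not loops:
        return mesh.copy(), 0.0
    verts = [mesh.vertices.copy()]
    faces = [mesh.faces.copy()]
    n = len(mesh.vertices)
    base_area = 0.0
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None])
        c_idx = n
        n += 1
        ring = np.stack([loop, np.roll(loop, -1)], axis=1)
        # boundary edges run counter the face orientation, so (b, a, c)
        # keeps cap normals consistent with the open surface
        cap = np.column_stack([ring[:, 1], ring[:, 0],
                               np.full(len(ring), c_idx)])
        faces.append(cap)
        p = mesh.vertices[ring[:, 0]] - centroid
        q = mesh.vertices[ring[:, 1]] - centroid
        base_area += 0.5 * np.linalg.norm(np.cross(p, q), axis=1).sum()
    capped = trimesh.Trimesh(vertices=np.vstack(verts),
                             faces=np.vstack(faces), process=False)
    return capped, float(base_area)


# ---------------------------------------------------------------------------
# analytic test meshes
# ---------------------------------------------------------------------------

def _grid_faces(ny: int, nx: int) -> np.ndarray:
    i, j = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (i * nx + j).ravel()
    v01 = v00 + 1
    v10 = v00 + nx
    v11 = v10 + 1
    return np.vstack([np.column_stack([v00, v10, v11]),
                      np.column_stack([v00, v11, v01])])


def make_grid_plane_mesh(ny: int, nx: int, spacing: float = 1.0) -> trimesh.Trimesh:
    """Flat triangulated plane in the z=0 plane (vertices (0, y, x))."""
    yy, xx = np.meshgrid(np.arange(ny) * spacing, np.arange(nx) * spacing,
                         indexing="ij")
    v = np.column_stack([np.zeros(yy.size), yy.ravel(), xx.ravel()])
    return trimesh.Trimesh(vertices=v, faces=_grid_faces(ny, nx), process=False)


def make_grid_disk_mesh(radius: float, spacing: float) -> trimesh.Trimesh:
    """Flat triangulated disk of given radius, from a trimmed grid.

    Useful as an analytic region: the geodesic distance to the rim is the
    Euclidean distance ``radius - r`` up to triangulation metrication.
    """
    n = int(np.ceil(2 * radius / spacing)) + 3
    plane = make_grid_plane_mesh(n, n, spacing)
    center = plane.vertices.mean(axis=0)
    keep_v = np.linalg.norm(plane.vertices - center, axis=1) <= radius
    keep_f = keep_v[plane.faces].all(axis=1)
    disk = trimesh.Trimesh(vertices=plane.vertices,
                           faces=plane.faces[keep_f], process=False)
    disk.remove_unreferenced_vertices()
    # keep only the largest connected patch in case trimming split corners
    parts = disk.split(only_watertight=False)
    if len(parts) > 1:
        disk = max(parts, key=lambda m: len(m.faces))
    return disk
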