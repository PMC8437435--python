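"""JMP detection on 3D light-sheet volumes.

The detector follows a mesh-morphometry chain: build a valid-region mask
(deskewed light-sheet frames are padded with zeros that would wreck any
global threshold), segment the membrane with an Otsu threshold inside that
mask, surface it with marching cubes at the physical voxel size, smooth the
mesh, compute a per-vertex "surface variation" statistic (volume of the
normal-aligned cylinder enclosing the vertex's graph n-neighborhood),
threshold and morphologically refine the labels, and finally cut out each
connected labeled patch, cap it into a watertight submesh, and measure its
volume (divergence theorem) and base area (area of the cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes

from . import meshops
from ._variation import variation_kernel
from .containers import (DegenerateInputError, ParameterError, VolumeFrame,
                         VolumeSeries)

log = logging.getLogger(__name__)

__all__ = [
    "VariationParams",
    "JMPRegion",
    "compute_valid_mask",
    "segment_membrane",
    "extract_surface",
    "smooth_mesh",
    "compute_surface_variation",
    "label_and_refine",
    "extract_regions",
    "detect_jmp_regions",
]

# re-export: smoothing lives with the generic mesh ops
smooth_mesh = meshops.smooth_mesh


@dataclass
class VariationParams:
    """Tunables of the variation statistic and label refinement.

    n_neighborhood
        Graph radius (in mesh edges) of the neighborhood enclosed by the
        cylinder; 20 by default.
    variation_threshold
        Global threshold on the cylinder volume (um^3 on physical-unit
        meshes) above which a vertex is labeled protrusive; 3.5 by default.
    smooth_iterations / smooth_ring
        Mean-smoothing passes applied before normals and variation.
    open_ring / close_ring
        Graph radii of the morphological opening and closing applied to
        the label set (1 and 5 by default).
    min_region_faces
        Labeled patches with fewer faces are discarded as mesh debris.
    """

    n_neighborhood: int = 20
    variation_threshold: float = 3.5
    smooth_iterations: int = 4
    smooth_ring: int = 1
    open_ring: int = 1
    close_ring: int = 5
    min_region_faces: int = 10

    def __post_init__(self) -> None:
        for name in ("n_neighborhood", "smooth_ring", "open_ring",
                     "close_ring", "min_region_faces"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.smooth_iterations < 0:
            raise ParameterError("smooth_iterations must be >= 0")
        if self.variation_threshold <= 0:
            raise ParameterError("variation_threshold must be > 0")


@dataclass
class JMPRegion:
    """A capped, closed protrusion submesh with its morphometry."""

    submesh: trimesh.Trimesh
    volume_um3: float
    base_area_um2: float
    frame_index: int = 0
    region_id: int = 0
    open_submesh: trimesh.Trimesh | None = field(default=None, repr=False)


def compute_valid_mask(series: VolumeSeries | VolumeFrame,
                       n_frames: int = 50) -> np.ndarray:
    """Valid-region mask: union of non-zero voxels over the first
    ``min(n_frames, T)`` frames, with 2D hole filling per z-slice.

    Deskewing tilted acquisitions pads each slice with a zero wedge; this
    mask confines all later thresholding to real data.
    """
    if isinstance(series, VolumeFrame):
        series = VolumeSeries([series])
    if series.n_frames == 0:
        raise ParameterError("empty series")
    mask = np.zeros(series[0].shape, dtype=bool)
    for frame in list(series)[:n_frames]:
        mask |= frame.data != 0
    if not mask.any():
        raise DegenerateInputError("all frames are entirely zero")
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])
    return mask


def segment_membrane(frame: VolumeFrame, valid_mask: np.ndarray,
                     small_fraction: float = 0.001,
                     hull_fraction: float = 0.5) -> np.ndarray:
    """Otsu-threshold the membrane inside the valid mask, then drop noise.

    Connected components smaller than ``small_fraction`` of the mask voxel
    count are discarded; components whose convex-hull volume exceeds
    ``hull_fraction`` of the mask volume are discarded as whole-frame noise
    bursts (an empty result is returned and the skip logged).
    """
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not valid_mask.any():
        raise ParameterError("valid mask is empty")
    inside = frame.data[valid_mask]
    if np.ptp(inside) == 0:
        raise DegenerateInputError("degenerate histogram: constant intensity "
                                   "within the valid mask")
    thr = threshold_otsu(inside)
    binary = (frame.data > thr) & valid_mask
    if not binary.any():
        return binary
    structure = np.ones((3, 3, 3), dtype=bool)
    lab, n_comp = ndimage.label(binary, structure=structure)
    counts = np.bincount(lab.ravel())
    mask_count = int(valid_mask.sum())
    min_voxels = small_fraction * mask_count
    keep = np.zeros(n_comp + 1, dtype=bool)
    for c in range(1, n_comp + 1):
        if counts[c] < min_voxels:
            continue
        hull_vol = _component_hull_volume(lab == c)
        if hull_vol > hull_fraction * mask_count:
            log.warning("frame %d: component hull spans %.0f%% of the mask; "
                        "skipping as a noise burst", frame.frame_index,
                        100 * hull_vol / mask_count)
            continue
        keep[c] = True
    return keep[lab]


def _component_hull_volume(comp: np.ndarray) -> float:
    """Convex-hull volume (voxel units) of a component's border voxels."""
    border = comp & ~ndimage.binary_erosion(comp)
    pts = np.argwhere(border)
    if len(pts) < 4:
        return float(len(pts))
    try:
        return float(ConvexHull(pts.astype(np.float64)).volume)
    except QhullError:  # coplanar component
        return 0.0


def extract_surface(binary: np.ndarray,
                    voxel_size_um: tuple[float, float, float]) -> trimesh.Trimesh:
    """Marching-cubes triangle mesh of a binary volume in physical units.

    Vertices are (z, y, x) micrometre coordinates scaled by the anisotropic
    voxel size; degenerate faces are removed.  Normals follow the marching
    cubes gradient convention and point out of the bright phase.
    """
    binary = np.asarray(binary)
    if not binary.any():
        raise DegenerateInputError("empty binary volume")
    verts, faces, _, _ = marching_cubes(binary.astype(np.float64), level=0.5,
                                        spacing=tuple(voxel_size_um))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return mesh


def compute_surface_variation(mesh: trimesh.Trimesh,
                              n_neighborhood: int = 20,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex surface variation (um^3) and a boundary flag.

    The neighborhood of a vertex is every vertex within ``n_neighborhood``
    mesh edges (BFS rings).  Its members are projected onto the vertex
    normal: the cylinder height is the extent of the projections and the
    radius the largest in-plane distance, and the statistic is
    ``pi * r^2 * h``.  Vertices whose neighborhood is truncated by an open
    mesh boundary are computed from the available vertices and flagged.
    """
    if n_neighborhood < 1:
        raise ParameterError("n_neighborhood must be >= 1")
    adj = meshops.vertex_adjacency(mesh)
    normals = np.asarray(mesh.vertex_normals, dtype=np.float64)
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    normals = normals / norms[:, None]
    values = variation_kernel(adj.indptr.astype(np.int64),
                              adj.indices.astype(np.int64),
                              np.asarray(mesh.vertices, dtype=np.float64),
                              normals, n_neighborhood)
    boundary = meshops.boundary_vertex_mask(mesh)
    if boundary.any():
        # flag every vertex whose n-ring may be clipped by the boundary
        flagged = meshops.dilate_labels(adj, boundary, n_neighborhood)
    else:
        flagged = boundary
    return values, flagged


def label_and_refine(mesh: trimesh.Trimesh, variation: np.ndarray,
                     params: VariationParams | None = None,
                     nuclear_mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold the variation field and refine the label set.

    Vertices above the global variation threshold are labeled, vertices
    inside a (manually drawn) nuclear exclusion region are forced off, the
    labels are opened (ring ``open_ring``) to kill specks, closed (ring
    ``close_ring``) to bridge gaps, and enclosed unlabeled holes filled.
    """
    params = params or VariationParams()
    labels = np.asarray(variation) > params.variation_threshold
    if nuclear_mask is not None:
        labels &= ~np.asarray(nuclear_mask, dtype=bool)
    adj = meshops.vertex_adjacency(mesh)
    labels = meshops.open_labels(adj, labels, params.open_ring)
    labels = meshops.close_labels(adj, labels, params.close_ring)
    boundary = meshops.boundary_vertex_mask(mesh)
    labels = meshops.fill_label_holes(adj, labels, boundary)
    if nuclear_mask is not None:
        labels &= ~np.asarray(nuclear_mask, dtype=bool)
    return labels


def extract_regions(mesh: trimesh.Trimesh, labels: np.ndarray,
                    frame_index: int = 0,
                    min_region_faces: int = 10) -> list[JMPRegion]:
    """Cut labeled patches into capped submeshes and measure them.

    A face belongs to a region when all three vertices are labeled; faces
    are grouped by shared-edge connectivity.  Each patch's boundary loops
    are capped by a fan to the loop centroid, the volume is taken from the
    divergence theorem on the watertight result and the base area is the
    total cap area.  Patches below ``min_region_faces`` are dropped.
    """
    labels = np.asarray(labels, dtype=bool)
    face_sel = labels[mesh.faces].all(axis=1)
    if not face_sel.any():
        return []
    sub_faces = mesh.faces[face_sel]
    patch = trimesh.Trimesh(vertices=mesh.vertices.copy(), faces=sub_faces,
                            process=False)
    patch.remove_unreferenced_vertices()
    parts = patch.split(only_watertight=False)
    regions: list[JMPRegion] = []
    rid = 0
    for part in sorted(parts, key=lambda m: -len(m.faces)):
        if len(part.faces) < min_region_faces:
            continue
        part = _drop_nonmanifold(part)
        if len(part.faces) < min_region_faces:
            continue
        capped, base_area = meshops.cap_submesh(part)
        if not capped.is_watertight:
            log.warning("region %d (frame %d): cap left boundary edges; "
                        "measuring anyway", rid, frame_index)
        volume = float(abs(capped.volume))
        regions.append(JMPRegion(submesh=capped, volume_um3=volume,
                                 base_area_um2=base_area,
                                 frame_index=frame_index, region_id=rid,
                                 open_submesh=part))
        rid += 1
    return regions


def _drop_nonmanifold(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Remove faces on edges shared by more than two faces."""
    edges = np.sort(mesh.edges, axis=1)
    _, inv, counts = np.unique(edges, axis=0, return_inverse=True,
                               return_counts=True)
    bad_edge = counts > 2
    if not bad_edge.any():
        return mesh
    bad_face = bad_edge[inv].reshape(-1, 3).any(axis=1)
    log.warning("dropping %d non-manifold faces", int(bad_face.sum()))
    out = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                          faces=mesh.faces[~bad_face], process=False)
    out.remove_unreferenced_vertices()
    return out


def detect_jmp_regions(frame: VolumeFrame, params: VariationParams | None = None,
                       valid_mask: np.ndarray | None = None,
                       nuclear_mask_vertices: np.ndarray | None = None,
                       ) -> tuple[list[JMPRegion], trimesh.Trimesh, np.ndarray, np.ndarray]:
    """Full single-frame chain: mask, segment, surface, smooth, variation,
    label, extract.

    Returns ``(regions, smoothed_mesh, variation, labels)``.
    ``nuclear_mask_vertices`` is an optional per-vertex boolean for the
    manual nuclear exclusion (see :func:`jmpkit.io.polygon_vertex_mask`).
    """
    params = params or VariationParams()
    if valid_mask is None:
        valid_mask = (frame.valid_mask if frame.valid_mask is not None
                      else compute_valid_mask(frame))
    binary = segment_membrane(frame, valid_mask)
    if not binary.any():
        empty = trimesh.Trimesh()
        return [], empty, np.empty(0), np.empty(0, dtype=bool)
    mesh = extract_surface(binary, frame.voxel_size_um)
    smoothed = smooth_mesh(mesh, iterations=params.smooth_iterations)
    variation, _ = compute_surface_variation(smoothed, params.n_neighborhood)
    labels = label_and_refine(smoothed, variation, params,
                              nuclear_mask=nuclear_mask_vertices)
    regions = extract_regions(smoothed, labels, frame.frame_index,
                              params.min_region_faces)
    return regions, smoothed, variation, labels
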