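"""Synthetic scene generators with exact ground truth.

Every input class the pipeline consumes can be generated here with known
truth, so each downstream stage is testable without any microscopy data:

* :func:`make_monolayer_scene` - a membrane-labeled endothelial monolayer
  movie (Voronoi cells, bright junction bands) with localized high-dynamics
  patches on the junctions, optional photobleaching, rigid drift and
  additive Gaussian noise (clipped at zero).
* :func:`make_membrane_volume` - a 3D membrane sheet (3 voxels thick)
  carrying solid hemisphere or half-cylinder-ridge protrusions whose
  volumes and base areas have closed forms, with optional deskew-style
  zero-padding wedges and anisotropic voxels (z-step 0.211 um by default).
* :func:`make_stain_volume` - a stain channel concentrated on a protrusion
  surface shell with edge-, uniform- or center-weighted distributions.
* :func:`make_fret_pair` - donor/acceptor channels mixed with a known
  bleed-through fraction over a known ratio map.
* :func:`make_tracks` - neutrophil tracks with crawling, lateral-migration,
  turning and diapedesis events whose classification flags are known by
  construction.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.segmentation import find_boundaries

from .containers import (ParameterError, TimeLapseStack, VolumeFrame)
from .tem import FRAME_INTERVAL_S, DiapedesisEvent, NeutrophilTrack

__all__ = [
    "DynamicPatch",
    "ProtrusionTruth",
    "Scene2D",
    "Scene3D",
    "FretScene",
    "TrackScene",
    "make_monolayer_scene",
    "make_membrane_volume",
    "make_stain_volume",
    "make_fret_pair",
    "make_tracks",
]

# default monolayer conditions: widefield membrane-label movies of a
# confluent monolayer; intensities in camera counts
CYTOPLASM_LEVEL = 50.0
JUNCTION_LEVEL = 150.0
MEMBRANE_3D_LEVEL = 100.0
BACKGROUND_3D_LEVEL = 10.0
SHEET_THICKNESS_VOXELS = 3   # thin enough to surface, thick enough to segment


@dataclass
class DynamicPatch:
    """A localized high-dynamics (JMP-like) spot on a junction."""

    center_xy_um: tuple[float, float]
    radius_um: float
    amplitude: float


@dataclass
class ProtrusionTruth:
    kind: str                      # "hemisphere" | "ridge"
    center_yx_um: tuple[float, float]
    radius_um: float
    analytic_volume_um3: float
    analytic_base_area_um2: float
    length_um: float | None = None
    axis: str | None = None


@dataclass
class Scene2D:
    stack: TimeLapseStack
    junction_mask: np.ndarray
    cell_labels: np.ndarray
    truth_dynamic_patches: list[DynamicPatch]
    bleach_rate: float
    drift: tuple[float, float]
    noise_sd: float
    patch_series: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stack.data.shape[1:] != self.junction_mask.shape:
            raise ParameterError("stack and mask dimensions differ")
        if self.junction_mask.shape != self.cell_labels.shape:
            raise ParameterError("mask and label dimensions differ")
        for p in self.truth_dynamic_patches:
            if p.amplitude <= 0:
                raise ParameterError("patch amplitude must be > 0")


@dataclass
class Scene3D:
    volume: VolumeFrame
    voxel_size_um: tuple[float, float, float]
    truth_protrusions: list[ProtrusionTruth]
    padding_mask: np.ndarray
    sheet_top_um: float
    noise_sd: float = 0.0


@dataclass
class FretScene:
    donor: TimeLapseStack
    acceptor: TimeLapseStack
    alpha_true: float
    ratio_true: np.ndarray
    background_level: float
    donor_signal: np.ndarray = field(repr=False, default=None)


@dataclass
class TrackScene:
    tracks: list[NeutrophilTrack]
    truth_events: list[DiapedesisEvent]
    scene: Scene2D
    frame_interval_s: float = FRAME_INTERVAL_S


# ---------------------------------------------------------------------------
# 2D monolayer movies
# ---------------------------------------------------------------------------

def make_monolayer_scene(n_cells: int = 6,
                         patch_spec: list[dict] | int = 2,
                         bleach_rate: float = 0.0,
                         drift: tuple[float, float] = (0.0, 0.0),
                         noise_sd: float = 2.0,
                         seed: int = 0,
                         shape: tuple[int, int, int] = (40, 256, 256),
                         pixel_size_um: float = 0.18,
                         frame_interval_s: float = 2.0) -> Scene2D:
    """Membrane-labeled monolayer movie with known dynamic junction patches.

    ``patch_spec`` is either the number of patches (random junction
    placement) or a list of ``{"center_xy_um", "radius_um", "amplitude"}``
    dicts; centers are snapped to the nearest junction pixel.  Patch
    intensity is modulated per frame by ``1 + amplitude * s_t`` with
    ``s_t`` drawn uniformly from [-1, 1], so the temporal CoV inside a
    patch is controlled by the amplitude.  Bleaching multiplies frame t by
    ``(1 - bleach_rate)**t``; drift translates frame t by ``t * (dy, dx)``
    pixels; noise is additive Gaussian clipped at zero.
    """
    if n_cells < 2:
        raise ParameterError("need at least 2 cells for a junction")
    rng = np.random.default_rng(seed)
    t, ny, nx = shape

    labels = _voronoi_labels(rng, n_cells, ny, nx)
    junction = find_boundaries(labels, mode="thick")
    jband = ndimage.binary_dilation(junction, iterations=2)
    base = np.where(jband, JUNCTION_LEVEL, CYTOPLASM_LEVEL)

    patches = _place_patches(rng, patch_spec, junction, pixel_size_um,
                             (ny, nx))
    # per-frame modulation factors, one row per patch
    series = rng.uniform(-1.0, 1.0, size=(len(patches), t))
    weights = []
    yy, xx = np.mgrid[:ny, :nx]
    for p in patches:
        cx, cy = p.center_xy_um
        r2 = ((yy - cy / pixel_size_um) ** 2 +
              (xx - cx / pixel_size_um) ** 2)
        weights.append(r2 <= (p.radius_um / pixel_size_um) ** 2)

    data = np.empty(shape, dtype=np.float64)
    for i in range(t):
        frame = base.copy()
        for p, w, s in zip(patches, weights, series[:, i] if len(patches)
                           else []):
            frame[w] *= 1.0 + p.amplitude * s
        frame *= (1.0 - bleach_rate) ** i
        dy, dx = drift[0] * i, drift[1] * i
        if dy or dx:
            if float(dy).is_integer() and float(dx).is_integer():
                frame = np.roll(frame, (int(dy), int(dx)), axis=(0, 1))
            else:
                frame = ndimage.shift(frame, (dy, dx), order=1,
                                      mode="grid-wrap")
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
            np.clip(frame, 0.0, None, out=frame)
        data[i] = frame

    stack = TimeLapseStack(data, pixel_size_um, frame_interval_s)
    return Scene2D(stack=stack, junction_mask=junction, cell_labels=labels,
                   truth_dynamic_patches=patches, bleach_rate=bleach_rate,
                   drift=tuple(drift), noise_sd=noise_sd,
                   patch_series=series)


def _voronoi_labels(rng, n_cells: int, ny: int, nx: int) -> np.ndarray:
    """Nearest-seed (Voronoi) cell labels 1..n_cells on a pixel grid."""
    # rejection-sample seeds with a minimum pairwise separation so cells
    # have usable interiors
    min_sep = 0.25 * min(ny, nx) / np.sqrt(n_cells)
    seeds: list[np.ndarray] = []
    for _ in range(10000):
        cand = rng.uniform([0.1 * ny, 0.1 * nx], [0.9 * ny, 0.9 * nx])
        if all(np.linalg.norm(cand - s) >= min_sep for s in seeds):
            seeds.append(cand)
        if len(seeds) == n_cells:
            break
    if len(seeds) < n_cells:
        raise ParameterError("could not place cell seeds; too many cells")
    pts = np.asarray(seeds)
    yy, xx = np.mgrid[:ny, :nx]
    d2 = ((yy[None] - pts[:, 0, None, None]) ** 2 +
          (xx[None] - pts[:, 1, None, None]) ** 2)
    return np.argmin(d2, axis=0) + 1


def _place_patches(rng, patch_spec, junction: np.ndarray,
                   pixel_size_um: float,
                   shape_yx: tuple[int, int]) -> list[DynamicPatch]:
    ny, nx = shape_yx
    jpix = np.argwhere(junction)
    if isinstance(patch_spec, int):
        patch_spec = [{"radius_um": 2.5, "amplitude": 0.5}
                      for _ in range(patch_spec)]
    patches = []
    margin_px = 0.15 * min(ny, nx)
    interior = jpix[(jpix[:, 0] > margin_px) & (jpix[:, 0] < ny - margin_px)
                    & (jpix[:, 1] > margin_px) & (jpix[:, 1] < nx - margin_px)]
    for spec in patch_spec:
        radius = float(spec.get("radius_um", 2.5))
        amplitude = float(spec.get("amplitude", 0.5))
        if amplitude <= 0:
            raise ParameterError("patch amplitude must be > 0")
        if radius / pixel_size_um >= min(ny, nx) / 2:
            raise ParameterError("patch radius exceeds image size")
        if "center_xy_um" in spec and spec["center_xy_um"] is not None:
            cx, cy = spec["center_xy_um"]
            rc = np.array([cy, cx]) / pixel_size_um
            near = jpix[np.argmin(((jpix - rc) ** 2).sum(axis=1))]
        else:
            cand = interior if len(interior) else jpix
            ok = cand
            if patches:
                prev = np.array([[p.center_xy_um[1], p.center_xy_um[0]]
                                 for p in patches]) / pixel_size_um
                sep = (2 * radius + 5.0) / pixel_size_um
                dist2 = ((cand[:, None, :] - prev[None]) ** 2).sum(axis=2)
                ok = cand[(dist2 > sep ** 2).all(axis=1)]
                if len(ok) == 0:
                    ok = cand
            near = ok[rng.integers(len(ok))]
        patches.append(DynamicPatch(
            center_xy_um=(near[1] * pixel_size_um, near[0] * pixel_size_um),
            radius_um=radius, amplitude=amplitude))
    return patches


# ---------------------------------------------------------------------------
# 3D membrane volumes
# ---------------------------------------------------------------------------

def make_membrane_volume(protrusion_spec: list[dict],
                         voxel_size_um: tuple[float, float, float]
                         = (0.211, 0.104, 0.104),
                         shape: tuple[int, int, int] = (48, 192, 192),
                         pad_style: str | None = None,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         sheet_z0: int = 6) -> Scene3D:
    """3D membrane sheet carrying protrusions of known morphometry.

    The sheet is ``SHEET_THICKNESS_VOXELS`` voxels thick and spans the full
    x-y extent so its marching-cubes surface is a pair of open sheets.
    Protrusions are generated as *solid* shapes fused onto the sheet top so
    the outer surface is a single closed cap with closed-form volume and
    base area (a hollow shell would mesh as two nested surfaces):

    * ``{"kind": "hemisphere", "center_yx_um": (y, x), "radius_um": r}``
      with volume ``(2/3) pi r^3`` and base area ``pi r^2``;
    * ``{"kind": "ridge", "center_yx_um": (y, x), "radius_um": r,
      "length_um": L, "axis": "y"|"x"}``: a half cylinder lying on the
      sheet, volume ``(1/2) pi r^2 L``, base area ``2 r L``.

    ``pad_style='deskew'`` zeroes a z-dependent x wedge, emulating the
    zero-padding deskewing introduces; the padding mask excludes it.
    """
    vz, vy, vx = voxel_size_um
    if min(voxel_size_um) <= 0:
        raise ParameterError("voxel sizes must be strictly positive")
    nz, ny, nx = shape
    if sheet_z0 + SHEET_THICKNESS_VOXELS >= nz:
        raise ParameterError("volume too shallow for the sheet")
    rng = np.random.default_rng(seed)

    truths = _protrusion_truths(protrusion_spec, (ny * vy, nx * vx))
    _check_overlap(truths)

    membrane = np.zeros(shape, dtype=bool)
    membrane[sheet_z0:sheet_z0 + SHEET_THICKNESS_VOXELS] = True
    # physical z of the sheet's top iso-surface (0.5-crossing above the
    # last membrane voxel layer)
    z_top = (sheet_z0 + SHEET_THICKNESS_VOXELS - 0.5) * vz

    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy
    xc = np.arange(nx) * vx
    for tr in truths:
        cy, cx = tr.center_yx_um
        r = tr.radius_um
        if z_top + r >= (nz - 1) * vz:
            raise ParameterError("protrusion taller than the volume")
        zz = zc[:, None, None] - z_top
        if tr.kind == "hemisphere":
            d2 = (zz ** 2 + (yc[None, :, None] - cy) ** 2 +
                  (xc[None, None, :] - cx) ** 2)
            inside = (d2 <= r ** 2) & (zz >= 0)
        else:  # ridge
            half = tr.length_um / 2.0
            if tr.axis == "y":
                rad2 = zz ** 2 + (xc[None, None, :] - cx) ** 2
                along = np.abs(yc[None, :, None] - cy)
            else:
                rad2 = zz ** 2 + (yc[None, :, None] - cy) ** 2
                along = np.abs(xc[None, None, :] - cx)
            inside = (rad2 <= r ** 2) & (zz >= 0) & (along <= half)
        membrane |= inside

    data = np.where(membrane, MEMBRANE_3D_LEVEL, BACKGROUND_3D_LEVEL)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=shape)
        np.clip(data, 0.0, None, out=data)

    padding = np.ones(shape, dtype=bool)
    if pad_style == "deskew":
        # shear-style parallelogram: each slice loses `off` columns on the
        # left and `max_off - off` on the right, with `off` growing with z
        max_off = nx // 6
        for z in range(nz):
            off = int(round(max_off * z / max(nz - 1, 1)))
            padding[z, :, :off] = False
            tail = max_off - off
            if tail:
                padding[z, :, nx - tail:] = False
        for tr in truths:
            cy, cx = tr.center_yx_um
            r = tr.radius_um
            jy = int(cy / vy)
            x0 = max(int((cx - r) / vx), 0)
            x1 = min(int((cx + r) / vx) + 1, nx)
            if not padding[:, jy, x0:x1].all():
                raise ParameterError("protrusion overlaps the padding wedge")
        data = np.where(padding, data, 0.0)
    elif pad_style is not None:
        raise ParameterError(f"unknown pad_style {pad_style!r}")

    volume = VolumeFrame(data=data, voxel_size_um=voxel_size_um,
                         valid_mask=padding)
    return Scene3D(volume=volume, voxel_size_um=voxel_size_um,
                   truth_protrusions=truths, padding_mask=padding,
                   sheet_top_um=z_top, noise_sd=noise_sd)


def _protrusion_truths(spec: list[dict],
                       extent_yx_um: tuple[float, float]) -> list[ProtrusionTruth]:
    truths = []
    for s in spec:
        kind = s.get("kind", "hemisphere")
        r = float(s["radius_um"])
        cy, cx = s["center_yx_um"]
        if r <= 0:
            raise ParameterError("protrusion radius must be > 0")
        if not (0 < cy < extent_yx_um[0] and 0 < cx < extent_yx_um[1]):
            raise ParameterError("protrusion center outside the volume")
        if kind == "hemisphere":
            truths.append(ProtrusionTruth(
                kind=kind, center_yx_um=(cy, cx), radius_um=r,
                analytic_volume_um3=(2.0 / 3.0) * np.pi * r ** 3,
                analytic_base_area_um2=np.pi * r ** 2))
        elif kind == "ridge":
            length = float(s["length_um"])
            axis = s.get("axis", "y")
            if axis not in ("y", "x"):
                raise ParameterError("ridge axis must be 'y' or 'x'")
            truths.append(ProtrusionTruth(
                kind=kind, center_yx_um=(cy, cx), radius_um=r,
                analytic_volume_um3=0.5 * np.pi * r ** 2 * length,
                analytic_base_area_um2=2.0 * r * length,
                length_um=length, axis=axis))
        else:
            raise ParameterError(f"unknown protrusion kind {kind!r}")
    return truths


def _footprint_radius(tr: ProtrusionTruth) -> float:
    if tr.kind == "hemisphere":
        return tr.radius_um
    return float(np.hypot(tr.length_um / 2.0, tr.radius_um))


def _check_overlap(truths: list[ProtrusionTruth]) -> None:
    for i in range(len(truths)):
        for j in range(i + 1, len(truths)):
            d = np.linalg.norm(np.subtract(truths[i].center_yx_um,
                                           truths[j].center_yx_um))
            if d <= _footprint_radius(truths[i]) + _footprint_radius(truths[j]):
                raise ParameterError("protrusions overlap")


def make_stain_volume(scene: Scene3D, mode: str = "uniform", seed: int = 0,
                      stain_level: float = 100.0,
                      background_level: float = 5.0,
                      noise_sd: float = 0.0,
                      edge_fraction: float = 0.1,
                      center_sigma: float = 0.35) -> VolumeFrame:
    """Stain channel concentrated on the protrusion surface shells.

    ``mode='edge'`` stains only shell voxels whose arc distance from the
    protrusion rim is within ``edge_fraction`` of the rim-to-apex arc;
    ``'uniform'`` stains the whole shell evenly; ``'center'`` weights the
    shell by a Gaussian in the polar angle peaking at the apex.
    """
    if mode not in ("edge", "uniform", "center"):
        raise ParameterError(f"unknown stain mode {mode!r}")
    if not scene.truth_protrusions:
        raise ParameterError("scene has no protrusions to stain")
    rng = np.random.default_rng(seed)
    vz, vy, vx = scene.voxel_size_um
    nz, ny, nx = scene.volume.shape
    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy
    xc = np.arange(nx) * vx
    data = np.full(scene.volume.shape, background_level, dtype=np.float64)
    shell_half = max(vz, vy, vx)
    for tr in scene.truth_protrusions:
        cy, cx = tr.center_yx_um
        r = tr.radius_um
        zz = zc[:, None, None] - scene.sheet_top_um
        if tr.kind == "hemisphere":
            dist = np.sqrt(zz ** 2 + (yc[None, :, None] - cy) ** 2 +
                           (xc[None, None, :] - cx) ** 2)
            axis_frac = np.clip(np.divide(zz, np.maximum(dist, 1e-12)), 0, 1)
        else:
            half = tr.length_um / 2.0
            if tr.axis == "y":
                rad = np.sqrt(zz ** 2 + (xc[None, None, :] - cx) ** 2)
                along = np.abs(yc[None, :, None] - cy)
            else:
                rad = np.sqrt(zz ** 2 + (yc[None, :, None] - cy) ** 2)
                along = np.abs(xc[None, None, :] - cx)
            dist = rad
            axis_frac = np.clip(np.divide(zz, np.maximum(rad, 1e-12)), 0, 1)
        shell = (np.abs(dist - r) <= shell_half) & (zz >= 0)
        if tr.kind == "ridge":
            shell &= along <= half
        theta = np.arccos(axis_frac)          # 0 at apex, pi/2 at rim
        if mode == "edge":
            sel = shell & (theta >= (np.pi / 2) * (1.0 - edge_fraction))
            data[sel] = stain_level
        elif mode == "uniform":
            data[shell] = stain_level
        else:  # center
            w = np.exp(-0.5 * (theta / center_sigma) ** 2)
            data[shell] = background_level + (stain_level
                                              - background_level) * w[shell]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    data = np.where(scene.padding_mask, data, 0.0)
    return VolumeFrame(data=data, voxel_size_um=scene.voxel_size_um,
                       valid_mask=scene.padding_mask)


# ---------------------------------------------------------------------------
# FRET pairs
# ---------------------------------------------------------------------------

def make_fret_pair(ratio_map: np.ndarray, alpha_true: float = 0.62,
                   background: float = 20.0, noise_sd: float = 0.0,
                   seed: int = 0, n_frames: int = 5,
                   donor_signal: np.ndarray | None = None,
                   pixel_size_um: float = 0.18) -> FretScene:
    """Donor/acceptor pair with known bleed-through and ratio.

    By construction ``acceptor = (ratio_true + alpha_true) * donor_signal
    + background + noise``.  The donor signal defaults to a smooth random
    blob field in [40, 160] counts.
    """
    ratio_map = np.asarray(ratio_map, dtype=np.float64)
    if not (0 <= alpha_true < 1):
        raise ParameterError("alpha_true must be in [0, 1)")
    if background < 0:
        raise ParameterError("background must be >= 0")
    rng = np.random.default_rng(seed)
    if donor_signal is None:
        raw = rng.normal(size=ratio_map.shape)
        blob = ndimage.gaussian_filter(raw, sigma=8)
        blob = (blob - blob.min()) / np.ptp(blob)
        donor_signal = 40.0 + 120.0 * blob
    donor_signal = np.asarray(donor_signal, dtype=np.float64)
    if donor_signal.shape != ratio_map.shape:
        raise ParameterError("donor signal and ratio map shapes differ")
    shape = (n_frames,) + ratio_map.shape
    d = np.broadcast_to(donor_signal + background, shape).copy()
    a = np.broadcast_to((ratio_map + alpha_true) * donor_signal + background,
                        shape).copy()
    if noise_sd > 0:
        d = np.clip(d + rng.normal(0, noise_sd, shape), 0, None)
        a = np.clip(a + rng.normal(0, noise_sd, shape), 0, None)
    return FretScene(
        donor=TimeLapseStack(d, pixel_size_um),
        acceptor=TimeLapseStack(a, pixel_size_um),
        alpha_true=alpha_true, ratio_true=ratio_map,
        background_level=background, donor_signal=donor_signal)


# ---------------------------------------------------------------------------
# neutrophil tracks
# ---------------------------------------------------------------------------

def make_tracks(scene: Scene2D, event_spec: list[dict],
                seed: int = 0, positional_noise_um: float = 0.0,
                lateral_distance_um: float = 15.0,
                crawl_step_um: float = 2.5,
                roll_step_um: float = 12.0) -> TrackScene:
    """Neutrophil tracks whose TEM classification flags are known.

    ``event_spec`` entries are dicts with ``kind`` in ``{"immediate",
    "lateral", "turn"}`` and an optional ``at_jmp`` bool (the diapedesis
    site is placed on a truth dynamic patch when true, well away from all
    patches when false) plus optional ``site_um``.  Tracks get a short
    rolling approach (12 um/frame), a crawling run inside the arrival cell
    (2.5 um/frame), and the event-specific ending; truth flags are set by
    construction, not by running the classifier.
    """
    rng = np.random.default_rng(seed)
    pixel = scene.stack.pixel_size_um
    junction = scene.junction_mask
    labels = scene.cell_labels
    ny, nx = junction.shape
    jpix = np.argwhere(junction)
    seeds_rc = _label_centroids(labels)

    patch_rc = np.array([[p.center_xy_um[1] / pixel, p.center_xy_um[0] / pixel]
                         for p in scene.truth_dynamic_patches]).reshape(-1, 2)
    patch_radius_px = np.array([p.radius_um / pixel
                                for p in scene.truth_dynamic_patches])

    costs = np.where(junction, 1.0, np.inf)
    tracks: list[NeutrophilTrack] = []
    events: list[DiapedesisEvent] = []
    for tid, spec in enumerate(event_spec):
        kind = spec.get("kind", "immediate")
        if kind not in ("immediate", "lateral", "turn"):
            raise ParameterError(f"unknown event kind {kind!r}")
        at_jmp = bool(spec.get("at_jmp", False))
        # the at_jmp flag refers to the diapedesis site, so the site is
        # chosen first (on a dynamic patch or well clear of all patches)
        site_rc = _choose_contact(rng, spec, jpix, patch_rc,
                                  patch_radius_px, at_jmp, pixel, (ny, nx))
        if kind == "lateral":
            # the neutrophil first touches the junction a known geodesic
            # distance away and crawls along it to the site; the walk is
            # restricted to the arrival cell's own border so the track
            # never strays onto another cell (which would make it a turn)
            arrival_label, adjacent_label = _flanking_labels(labels, site_rc)
            border = ndimage.binary_dilation(
                labels == arrival_label, iterations=2) & junction
            costs_a = np.where(border, 1.0, np.inf)
            contact_rc, path = _along_junction_target(
                costs_a, site_rc, lateral_distance_um, pixel)
            path = path[::-1]          # walk contact -> site
        else:
            contact_rc = site_rc
            arrival_label, adjacent_label = _flanking_labels(labels,
                                                             contact_rc)
        seed_rc = seeds_rc[arrival_label]

        pos = _approach_positions(contact_rc, seed_rc, crawl_step_um,
                                  roll_step_um, pixel, (ny, nx),
                                  labels, arrival_label)
        if kind == "lateral":
            offs = _offset_path(path, seed_rc, 1.2 / pixel, (ny, nx),
                                crawl_step_um / pixel)
            # the frame before diapedesis must carry the arrival label
            offs = [_nudge_to_label(p, arrival_label, labels, seed_rc, pixel)
                    for p in offs]
            pos += offs
        elif kind == "turn":
            adj_seed = seeds_rc[adjacent_label]
            v = adj_seed - contact_rc
            v = v / np.linalg.norm(v)
            q = contact_rc + v * (2.0 / pixel)
            q = _nudge_to_label(q, adjacent_label, labels, adj_seed, pixel)
            pos.append(q)
        if kind != "immediate":
            # final frame back on the junction at the diapedesis site; for
            # immediate events the approach already ends there, and the
            # frame before diapedesis must stay on the arrival side
            pos.append(site_rc.astype(np.float64))
        pos = np.asarray(pos, dtype=np.float64)
        if positional_noise_um > 0:
            pos = pos + rng.normal(0, positional_noise_um / pixel, pos.shape)
        xy_um = np.column_stack([pos[:, 1], pos[:, 0]]) * pixel
        n = len(pos)
        site_xy_um = (site_rc[1] * pixel, site_rc[0] * pixel)
        track = NeutrophilTrack(
            track_id=tid, t_s=np.arange(n) * FRAME_INTERVAL_S,
            positions_um=xy_um, diapedesis_frame=n - 1,
            diapedesis_site=site_xy_um)
        tracks.append(track)
        events.append(DiapedesisEvent(
            track_id=tid, site=site_xy_um, frame=n - 1,
            first_junction=True,
            immediate=(kind != "lateral"),
            lateral=(kind == "lateral"),
            turn=(kind == "turn"),
            at_jmp=at_jmp))
    return TrackScene(tracks=tracks, truth_events=events, scene=scene)


def _label_centroids(labels: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        out[int(lab)] = np.array(ndimage.center_of_mass(labels == lab))
    return out


def _choose_contact(rng, spec, jpix, patch_rc, patch_radius_px, at_jmp,
                    pixel, shape_yx):
    ny, nx = shape_yx
    if spec.get("site_um") is not None:
        cx, cy = spec["site_um"]
        rc = np.array([cy, cx]) / pixel
        d2 = ((jpix - rc) ** 2).sum(axis=1)
        if d2.min() > 1.5 ** 2:
            raise ParameterError("requested event site is off the junction")
        return jpix[np.argmin(d2)].astype(np.float64)
    if at_jmp:
        if len(patch_rc) == 0:
            raise ParameterError("at_jmp event needs dynamic patches")
        k = rng.integers(len(patch_rc))
        return patch_rc[k].copy()
    margin = 0.12 * min(ny, nx)
    inner = jpix[(jpix[:, 0] > margin) & (jpix[:, 0] < ny - margin) &
                 (jpix[:, 1] > margin) & (jpix[:, 1] < nx - margin)]
    cand = inner if len(inner) else jpix
    if len(patch_rc):
        d2 = ((cand[:, None, :] - patch_rc[None]) ** 2).sum(axis=2)
        clear = (np.sqrt(d2) > (patch_radius_px[None] + 5.0 / pixel)).all(axis=1)
        if clear.any():
            cand = cand[clear]
    return cand[rng.integers(len(cand))].astype(np.float64)


def _flanking_labels(labels: np.ndarray, rc: np.ndarray) -> tuple[int, int]:
    """The two most common cell labels around a junction pixel."""
    r, c = int(round(rc[0])), int(round(rc[1]))
    r0, r1 = max(r - 4, 0), min(r + 5, labels.shape[0])
    c0, c1 = max(c - 4, 0), min(c + 5, labels.shape[1])
    vals, counts = np.unique(labels[r0:r1, c0:c1], return_counts=True)
    order = vals[np.argsort(-counts)]
    if len(order) < 2:
        raise ParameterError("junction pixel not between two cells")
    return int(order[0]), int(order[1])


def _approach_positions(contact_rc, seed_rc, crawl_step_um, roll_step_um,
                        pixel, shape_yx, labels=None,
                        arrival_label=None) -> list[np.ndarray]:
    """Rolling prefix plus a crawl inside the (convex) arrival cell.

    Rolling-phase points must stay on the arrival cell (rolling frames
    that cross other junctions would be ambiguous contacts); the prefix is
    dropped when the cell is too small for it.
    """
    ny, nx = shape_yx
    v = seed_rc - contact_rc
    norm = np.linalg.norm(v)
    if norm == 0:
        v = np.array([1.0, 0.0])
        norm = 1.0
    u = v / norm
    crawl_px = crawl_step_um / pixel
    start_dist = min(4 * crawl_px, 0.8 * norm)
    n_crawl = max(int(np.ceil(start_dist / crawl_px)), 2)
    # ends exactly on the contact point so the first junction contact is
    # the intended pixel
    crawl = [contact_rc + u * start_dist * (1 - k / n_crawl)
             for k in range(n_crawl + 1)]
    roll_px = roll_step_um / pixel
    rolls = []
    for k in (2, 1):
        p = contact_rc + u * (start_dist + k * roll_px)
        ok = 1 <= p[0] < ny - 2 and 1 <= p[1] < nx - 2
        if ok and labels is not None:
            r, c = int(round(p[0])), int(round(p[1]))
            ok = labels[r, c] == arrival_label
        if ok:
            rolls.append(p)
        else:
            rolls = []
            break
    return rolls + crawl


def _nudge_to_label(p: np.ndarray, want: int, labels: np.ndarray,
                    toward: np.ndarray, pixel: float,
                    max_um: float = 4.0) -> np.ndarray:
    """Move a point toward ``toward`` until it sits on the wanted label."""
    q = np.asarray(p, dtype=np.float64).copy()
    v = np.asarray(toward, dtype=np.float64) - q
    n = np.linalg.norm(v)
    if n == 0:
        return q
    step = v / n * (0.5 / pixel)
    for _ in range(int(max_um / 0.5)):
        r = int(np.clip(round(q[0]), 0, labels.shape[0] - 1))
        c = int(np.clip(round(q[1]), 0, labels.shape[1] - 1))
        if labels[r, c] == want:
            return q
        q = q + step
    return q


def _along_junction_target(costs, contact_rc, distance_um, pixel):
    """A junction pixel ``distance_um`` along the junction, plus the path."""
    start = (int(round(contact_rc[0])), int(round(contact_rc[1])))
    mcp = MCP_Geometric(costs)
    dists, _ = mcp.find_costs([start])
    target_px = distance_um / pixel
    ok = np.isfinite(dists) & (dists >= target_px)
    if not ok.any():
        raise ParameterError("junction too short for the lateral distance")
    cand = np.argwhere(ok)
    best = cand[np.argmin(dists[ok.nonzero()])]
    path = np.asarray(mcp.traceback(tuple(best)), dtype=np.float64)
    return best.astype(np.float64), path


def _offset_path(path, seed_rc, offset_px, shape_yx, step_px):
    """Resample a junction path at the crawl step, nudged toward the
    arrival cell so intermediate frames sit on the arrival side."""
    ny, nx = shape_yx
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0], np.cumsum(steps)])
    n = max(int(cum[-1] // step_px), 1)
    out = []
    for k in range(1, n):
        s = k * step_px
        i = np.searchsorted(cum, s)
        i = min(i, len(path) - 1)
        p = path[i].astype(np.float64)
        v = seed_rc - p
        nv = np.linalg.norm(v)
        if nv > 0:
            p = p + v / nv * offset_px
        p[0] = np.clip(p[0], 0, ny - 1)
        p[1] = np.clip(p[1], 0, nx - 1)
        out.append(p)
    return out
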