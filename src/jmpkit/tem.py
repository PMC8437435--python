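"""Rule-based classification of neutrophil transendothelial migration (TEM).

Neutrophil positions (manually tracked, one point per 5 s frame) are scored
against the endothelial junction mask, the cell-label image and membrane
dynamics maps:

* crawling vs rolling by a 10 um / 5 s displacement rule;
* whether diapedesis happened at the first junction encountered, whether
  the cell migrated laterally along the junction (> 10 um along the
  skeleton) before crossing, and whether it turned onto the adjacent
  endothelial cell just before diapedesis;
* whether the diapedesis site sits on a JMP: the site's value in a
  dynamics map built from pre-arrival frames exceeds twice the map mean;
* the relative membrane-dynamics increase between the diapedesis site and
  the first junction contact, and the before/after change around a TEM
  event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .containers import DegenerateInputError, ParameterError, TimeLapseStack
from .dynamics import DynamicsMap, compute_dynamics_map

__all__ = [
    "NeutrophilTrack",
    "DiapedesisEvent",
    "classify_phases",
    "junction_encounter_stats",
    "diapedesis_at_jmp",
    "relative_md_increase",
    "jmp_change_after_tem",
]

CRAWLING_SPEED_UM_PER_FRAME = 10.0   # below -> crawling; at/above -> rolling
LATERAL_DISTANCE_UM = 10.0           # along-junction migration beyond this
AT_JMP_FACTOR = 2.0                  # site value vs map mean
FRAME_INTERVAL_S = 5.0


@dataclass
class NeutrophilTrack:
    """Timed neutrophil positions in physical units.

    ``positions_um`` has one (x, y) row per frame at a constant 5 s
    spacing; ``diapedesis_frame``/``diapedesis_site`` mark the breaching
    step when it happens.
    """

    track_id: int
    t_s: np.ndarray
    positions_um: np.ndarray            # (N, 2) columns (x_um, y_um)
    diapedesis_frame: int | None = None
    diapedesis_site: tuple[float, float] | None = None   # (x_um, y_um)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        if len(self.t_s) != len(self.positions_um):
            raise ParameterError("time and position lengths differ")
        if len(self.t_s) >= 2 and np.any(np.diff(self.t_s) <= 0):
            raise ParameterError("timestamps must be strictly increasing")


@dataclass
class DiapedesisEvent:
    track_id: int
    site: tuple[float, float]
    frame: int
    first_junction: bool | None = None
    immediate: bool | None = None
    lateral: bool | None = None
    turn: bool | None = None
    at_jmp: bool | None = None
    md_relative_increase: float | None = None
    jmp_ratio_after_before: float | None = None
    notes: list[str] = field(default_factory=list)


def classify_phases(track: NeutrophilTrack,
                    frame_interval_s: float = FRAME_INTERVAL_S) -> np.ndarray:
    """Per-frame phase: 'crawling' when the interval displacement is below
    10 um per 5 s frame, 'rolling' otherwise (10 um exactly is rolling).

    Intervals spanning missing frames (time gap larger than the nominal
    spacing) are skipped and marked 'gap'.
    """
    n = len(track.t_s)
    if n < 2:
        raise ParameterError("need at least 2 frames")
    disp = np.linalg.norm(np.diff(track.positions_um, axis=0), axis=1)
    dt = np.diff(track.t_s)
    phases = np.empty(n, dtype=object)
    for i in range(n - 1):
        if dt[i] > 1.5 * frame_interval_s:
            phases[i] = "gap"
        elif disp[i] < CRAWLING_SPEED_UM_PER_FRAME * dt[i] / frame_interval_s:
            phases[i] = "crawling"
        else:
            phases[i] = "rolling"
    phases[-1] = phases[-2]
    return phases


def _to_px(xy_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """(x, y) micrometre coordinates -> (row, col) pixel coordinates."""
    xy = np.atleast_2d(np.asarray(xy_um, dtype=np.float64))
    return np.column_stack([xy[:, 1], xy[:, 0]]) / pixel_size_um


def _junction_geodesic_um(junction: np.ndarray, start_rc: tuple[int, int],
                          end_rc: tuple[int, int],
                          pixel_size_um: float) -> float:
    """Shortest along-junction path length between two junction pixels."""
    costs = np.where(junction, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    dists, _ = mcp.find_costs([start_rc], [end_rc])
    d = dists[end_rc]
    return float(d * pixel_size_um) if np.isfinite(d) else np.inf


def junction_encounter_stats(track: NeutrophilTrack, junction_mask: np.ndarray,
                             cell_labels: np.ndarray, pixel_size_um: float,
                             contact_tol_px: float = 1.0) -> DiapedesisEvent:
    """First-junction / lateral / turn flags for one diapedesis event.

    The first junction contact is the first crawling-phase frame whose
    position comes within ``contact_tol_px`` of the junction mask.
    ``first_junction`` is true when the diapedesis site lies on the same
    connected junction component; ``lateral`` when the along-junction
    (geodesic) distance from the contact point to the site exceeds 10 um;
    ``turn`` when the cell label under the neutrophil the frame before
    diapedesis differs from the arrival-side label.
    """
    if track.diapedesis_frame is None or track.diapedesis_site is None:
        raise ParameterError("track has no diapedesis annotation")
    junction = np.asarray(junction_mask, dtype=bool)
    labels_img = np.asarray(cell_labels)
    if junction.shape != labels_img.shape:
        raise ParameterError("mask shapes differ")
    event = DiapedesisEvent(track_id=track.track_id,
                            site=tuple(track.diapedesis_site),
                            frame=int(track.diapedesis_frame))

    dist_px, (ind_r, ind_c) = ndimage.distance_transform_edt(
        ~junction, return_indices=True)
    pos_px = _to_px(track.positions_um, pixel_size_um)
    rows = np.clip(np.round(pos_px[:, 0]).astype(int), 0, junction.shape[0] - 1)
    cols = np.clip(np.round(pos_px[:, 1]).astype(int), 0, junction.shape[1] - 1)
    phases = classify_phases(track)
    diap = int(track.diapedesis_frame)
    contact_frame = None
    for i in range(min(len(rows), diap + 1)):
        if phases[i] != "crawling":
            continue
        if dist_px[rows[i], cols[i]] <= contact_tol_px:
            contact_frame = i
            break
    if contact_frame is None:
        # a diapedesis event implies the junction was touched; with noisy
        # (e.g. manually clicked) positions no frame may pass the strict
        # tolerance, so fall back to the closest crawling-phase approach
        crawl = [i for i in range(min(len(rows), diap + 1))
                 if phases[i] == "crawling"]
        if crawl:
            contact_frame = min(crawl, key=lambda i: dist_px[rows[i], cols[i]])
            event.notes.append("nearest-approach contact (no frame within "
                               "tolerance)")
        else:
            event.notes.append("no junction contact")
            return event

    contact_rc = (ind_r[rows[contact_frame], cols[contact_frame]],
                  ind_c[rows[contact_frame], cols[contact_frame]])
    site_px = _to_px(np.asarray(track.diapedesis_site), pixel_size_um)[0]
    sr = int(np.clip(round(site_px[0]), 0, junction.shape[0] - 1))
    sc = int(np.clip(round(site_px[1]), 0, junction.shape[1] - 1))
    site_rc = (ind_r[sr, sc], ind_c[sr, sc])

    comp, _ = ndimage.label(junction, structure=np.ones((3, 3), dtype=bool))
    event.first_junction = bool(comp[contact_rc] == comp[site_rc])
    along = _junction_geodesic_um(junction, contact_rc, site_rc, pixel_size_um)
    event.lateral = bool(event.first_junction and along > LATERAL_DISTANCE_UM)
    event.immediate = bool(event.first_junction and not event.lateral)

    arrival_frame = max(contact_frame - 1, 0)
    arrival_label = labels_img[rows[arrival_frame], cols[arrival_frame]]
    pre_frame = max(int(track.diapedesis_frame) - 1, 0)
    pre_label = labels_img[rows[pre_frame], cols[pre_frame]]
    event.turn = bool(pre_label != arrival_label and pre_label > 0
                      and arrival_label > 0)
    event.notes.append(f"contact_frame={contact_frame}")
    return event


def _disk_mean(values: np.ndarray, center_xy_um: tuple[float, float],
               radius_um: float, pixel_size_um: float) -> float:
    rc = _to_px(np.asarray(center_xy_um), pixel_size_um)[0]
    rr, cc = np.ogrid[:values.shape[0], :values.shape[1]]
    disk = ((rr - rc[0]) ** 2 + (cc - rc[1]) ** 2) <= (radius_um / pixel_size_um) ** 2
    sel = disk & np.isfinite(values)
    if not sel.any():
        raise DegenerateInputError("no defined map pixels in the region")
    return float(values[sel].mean())


def diapedesis_at_jmp(event: DiapedesisEvent, pre_arrival_map: DynamicsMap,
                      site_radius_um: float = 1.0) -> bool | None:
    """JMP call: site value in the pre-arrival dynamics map > 2x map mean.

    The map must be built from frames collected before the neutrophil
    arrived, so neutrophil-induced membrane motion does not leak into the
    statistic.  Returns None (and notes the event) when the site falls in
    an undefined map area; the comparison is strict, so a value of exactly
    twice the mean is not a JMP.
    """
    try:
        site_val = _disk_mean(pre_arrival_map.values, event.site,
                              site_radius_um, pre_arrival_map.pixel_size_um)
    except DegenerateInputError:
        event.notes.append("site in undefined map area")
        event.at_jmp = None
        return None
    mean_val = pre_arrival_map.summary_mean()
    event.at_jmp = bool(site_val > AT_JMP_FACTOR * mean_val)
    return event.at_jmp


def relative_md_increase(dmap: DynamicsMap, site_xy_um: tuple[float, float],
                         contact_xy_um: tuple[float, float],
                         site_radius_um: float = 5.0,
                         contact_radius_um: float = 10.0) -> float:
    """Relative membrane-dynamics increase at the diapedesis site.

    Region 1 is a disk (default radius 5 um) at the diapedesis site,
    region 2 a 10 um region at the first junction contact; the statistic
    is ``(mean1 - mean2) / mean2``.
    """
    m1 = _disk_mean(dmap.values, site_xy_um, site_radius_um,
                    dmap.pixel_size_um)
    m2 = _disk_mean(dmap.values, contact_xy_um, contact_radius_um,
                    dmap.pixel_size_um)
    if m2 <= 0:
        raise DegenerateInputError("reference region mean is not positive")
    return (m1 - m2) / m2


def jmp_change_after_tem(stack: TimeLapseStack,
                         site_xy_um: tuple[float, float],
                         arrival_frame: int, leave_frame: int,
                         site_radius_um: float = 5.0, n_after: int = 30,
                         mode: str = "relative") -> float:
    """Membrane-dynamics change at a diapedesis site across a TEM event.

    Value 1 is the dynamics-map summary over the site disk computed from
    the frames before arrival; value 2 from the ``n_after`` (default 30)
    frames after the neutrophil left.  ``mode='relative'`` returns
    ``(v2 - v1)/v1`` (the Methods formula); ``mode='ratio'`` returns
    ``v2/v1``.
    """
    if mode not in ("relative", "ratio"):
        raise ParameterError("mode must be 'relative' or 'ratio'")
    if arrival_frame < 2:
        raise ParameterError(f"only {arrival_frame} frames before arrival; "
                             "need >= 2")
    n_post = min(n_after, stack.n_frames - leave_frame)
    if n_post < 2:
        raise ParameterError(f"only {n_post} frames after leaving; need >= 2")
    pre = stack.copy()
    pre.data = stack.data[:arrival_frame]
    post = stack.copy()
    post.data = stack.data[leave_frame:leave_frame + n_after]
    v1 = _disk_mean(compute_dynamics_map(pre).values, site_xy_um,
                    site_radius_um, stack.pixel_size_um)
    v2 = _disk_mean(compute_dynamics_map(post).values, site_xy_um,
                    site_radius_um, stack.pixel_size_um)
    if v1 <= 0:
        raise DegenerateInputError("pre-TEM value is not positive")
    return v2 / v1 if mode == "ratio" else (v2 - v1) / v1
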