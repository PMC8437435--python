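"""Reading and writing the pipeline's on-disk formats.

TIFF stacks carry the pixel size as resolution metadata (pixels per
micrometre); dynamics/ratio maps are 32-bit float TIFFs with undefined
pixels encoded as NaN; tables are plain CSV; parameters travel as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ParameterError, TimeLapseStack, VolumeFrame
from .tem import FRAME_INTERVAL_S, NeutrophilTrack

__all__ = [
    "write_stack", "read_stack", "write_map", "read_map",
    "write_volume", "read_volume",
    "write_tracks_csv", "read_tracks_csv",
    "write_regions_csv", "load_params", "save_params",
    "polygon_vertex_mask", "export_region_mesh",
]


def _resolution(pixel_size_um: float):
    return (1.0 / pixel_size_um, 1.0 / pixel_size_um)


def write_stack(path: str | Path, stack: TimeLapseStack) -> None:
    tifffile.imwrite(
        path, stack.data.astype(np.float32), photometric="minisblack",
        resolution=_resolution(stack.pixel_size_um), resolutionunit="MICROMETER",
        metadata={"axes": "TYX",
                  "frame_interval_s": stack.frame_interval_s,
                  "pixel_size_um": stack.pixel_size_um})


def read_stack(path: str | Path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> TimeLapseStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
    if pixel_size_um is None:
        raise ParameterError("pixel size not in metadata; pass pixel_size_um")
    frame_interval_s = (frame_interval_s or meta.get("frame_interval_s")
                        or FRAME_INTERVAL_S)
    return TimeLapseStack(np.asarray(data, dtype=np.float64),
                          float(pixel_size_um), float(frame_interval_s))


def write_map(path: str | Path, values: np.ndarray,
              pixel_size_um: float) -> None:
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32),
                     photometric="minisblack",
                     resolution=_resolution(pixel_size_um),
                     resolutionunit="MICROMETER",
                     metadata={"pixel_size_um": pixel_size_um})


def read_map(path: str | Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return data, meta.get("pixel_size_um")


def write_volume(path: str | Path, volume: VolumeFrame) -> None:
    vz, vy, vx = volume.voxel_size_um
    tifffile.imwrite(path, volume.data.astype(np.float32),
                     photometric="minisblack",
                     resolution=(1.0 / vx, 1.0 / vy),
                     resolutionunit="MICROMETER",
                     metadata={"axes": "ZYX", "voxel_size_um": [vz, vy, vx]})


def read_volume(path: str | Path,
                voxel_size_um: tuple[float, float, float] | None = None
                ) -> VolumeFrame:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    voxel = voxel_size_um or meta.get("voxel_size_um")
    if voxel is None:
        raise ParameterError("voxel size not in metadata; pass voxel_size_um")
    return VolumeFrame(data, tuple(float(v) for v in voxel))


def write_tracks_csv(path: str | Path,
                     tracks: list[NeutrophilTrack]) -> None:
    rows = []
    for tr in tracks:
        for i, ((x, y), t) in enumerate(zip(tr.positions_um, tr.t_s)):
            rows.append({
                "track_id": tr.track_id, "frame": i, "t_s": t,
                "x_um": x, "y_um": y,
                "diapedesis_frame": tr.diapedesis_frame
                if tr.diapedesis_frame is not None else "",
                "site_x_um": tr.diapedesis_site[0]
                if tr.diapedesis_site else "",
                "site_y_um": tr.diapedesis_site[1]
                if tr.diapedesis_site else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[NeutrophilTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        diap = g["diapedesis_frame"].dropna()
        diap_frame = int(diap.iloc[0]) if len(diap) else None
        site = None
        if "site_x_um" in g and g["site_x_um"].notna().any():
            site = (float(g["site_x_um"].dropna().iloc[0]),
                    float(g["site_y_um"].dropna().iloc[0]))
        t_s = (g["t_s"].to_numpy(float) if "t_s" in g
               else g["frame"].to_numpy(float) * FRAME_INTERVAL_S)
        tracks.append(NeutrophilTrack(
            track_id=int(tid), t_s=t_s,
            positions_um=g[["x_um", "y_um"]].to_numpy(float),
            diapedesis_frame=diap_frame, diapedesis_site=site))
    return tracks


def write_regions_csv(path: str | Path, regions) -> None:
    pd.DataFrame([{
        "frame": r.frame_index, "region_id": r.region_id,
        "volume_um3": r.volume_um3, "base_area_um2": r.base_area_um2,
    } for r in regions]).to_csv(path, index=False)


def load_params(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_params(path: str | Path, params: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)


def polygon_vertex_mask(mesh, polygon_xy_um: np.ndarray) -> np.ndarray:
    """Per-vertex mask of a 2D polygon projected through z.

    The polygon is given as (x_um, y_um) vertex rows (e.g. a manually
    drawn nuclear exclusion ROI); a mesh vertex (z, y, x) is inside when
    its (x, y) projection is, by even-odd ray casting.
    """
    poly = np.asarray(polygon_xy_um, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ParameterError("polygon needs at least 3 vertices")
    px = np.asarray(mesh.vertices)[:, 2]
    py = np.asarray(mesh.vertices)[:, 1]
    inside = np.zeros(len(px), dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        crosses = ((y0 > py) != (y1 > py))
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < xint)
        x0, y0 = x1, y1
    return inside


def export_region_mesh(path: str | Path, mesh,
                       variation: np.ndarray | None = None,
                       labels: np.ndarray | None = None) -> None:
    """Write a mesh as PLY with optional per-vertex attributes."""
    out = mesh.copy()
    if variation is not None:
        out.vertex_attributes["surface_variation"] = np.asarray(
            variation, dtype=np.float32)
    if labels is not None:
        out.vertex_attributes["jmp_label"] = np.asarray(
            labels, dtype=np.uint8)
    out.export(str(path))
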