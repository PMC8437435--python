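"""Rac1 FRET biosensor ratio processing.

The biosensor reports Rac1 activity as the ratio of acceptor (mVenus) to
donor (Cerulean3) emission.  Raw channels are background-corrected against
a cell-free ROI, co-registered by translation, smoothed with a 3x3 mean,
and the donor bleed-through into the acceptor channel is removed as
``acceptor - alpha * donor`` (alpha = 0.62 for this sensor/filter set)
before dividing by the donor.  Read-outs: a median split of the 1 um
junction band into high/low Rac1 (used to score diapedesis sites) and
paired JMP-ROI versus 3 um junction-band means per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .containers import DegenerateInputError, ParameterError, TimeLapseStack

log = logging.getLogger(__name__)

__all__ = [
    "RatioMap",
    "preprocess_fret",
    "compute_ratio",
    "junction_band_mask",
    "junction_rac_map",
    "score_site",
    "jmp_fret_comparison",
]

DEFAULT_ALPHA = 0.62
#: donor floor, as a fraction of the donor's foreground mean
DONOR_EPS_FRACTION = 0.01


@dataclass
class RatioMap:
    """Per-pixel acceptor/donor ratio; undefined pixels are NaN."""

    values: np.ndarray
    pixel_size_um: float
    n_clipped: int = 0   # pixels whose corrected acceptor went negative

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def preprocess_fret(donor: TimeLapseStack, acceptor: TimeLapseStack,
                    background_roi: np.ndarray,
                    ) -> tuple[TimeLapseStack, TimeLapseStack, np.ndarray]:
    """Background-correct, register and smooth a donor/acceptor pair.

    Per frame, the mean of the (cell-free) background ROI is subtracted
    from each channel; the acceptor is registered onto the donor by
    translation-only phase correlation; both channels get a 3x3 uniform
    mean filter.  Smoothing precedes the bleed-through arithmetic done in
    :func:`compute_ratio`.  Returns the corrected stacks and the per-frame
    acceptor offsets.
    """
    roi = np.asarray(background_roi, dtype=bool)
    if not roi.any():
        raise ParameterError("background ROI is empty")
    if donor.data.shape != acceptor.data.shape:
        raise ParameterError("channel shapes differ")
    d = donor.data.astype(np.float64).copy()
    a = acceptor.data.astype(np.float64).copy()
    offsets = np.zeros((d.shape[0], 2))
    for t in range(d.shape[0]):
        bg_d = d[t][roi].mean()
        bg_a = a[t][roi].mean()
        if bg_d > d[t].mean() or bg_a > a[t].mean():
            log.warning("frame %d: background ROI brighter than the frame "
                        "mean; suspect ROI placement", t)
        d[t] -= bg_d
        a[t] -= bg_a
        shift, _, _ = phase_cross_correlation(d[t], a[t], upsample_factor=10,
                                              normalization=None)
        offsets[t] = shift
        if np.any(shift != 0):
            a[t] = ndimage.shift(a[t], shift, order=1, mode="nearest")
        d[t] = ndimage.uniform_filter(d[t], size=3, mode="nearest")
        a[t] = ndimage.uniform_filter(a[t], size=3, mode="nearest")
    out_d, out_a = donor.copy(), acceptor.copy()
    out_d.data, out_a.data = d, a
    return out_d, out_a, offsets


def compute_ratio(donor: np.ndarray | TimeLapseStack,
                  acceptor: np.ndarray | TimeLapseStack,
                  alpha: float = DEFAULT_ALPHA,
                  pixel_size_um: float = 1.0) -> RatioMap:
    """Bleed-through-corrected FRET ratio ``(acceptor - alpha*donor)/donor``.

    Pixels whose donor is at or below the floor (1% of the donor
    foreground mean) are undefined; pixels whose corrected acceptor is
    negative are clipped to undefined and counted.  Stacks are averaged
    over time before the division (a per-frame map can be had by passing
    single frames).
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    if isinstance(donor, TimeLapseStack):
        pixel_size_um = donor.pixel_size_um
        donor = donor.data
    if isinstance(acceptor, TimeLapseStack):
        acceptor = acceptor.data
    d = np.asarray(donor, dtype=np.float64)
    a = np.asarray(acceptor, dtype=np.float64)
    if d.ndim == 3:
        d = d.mean(axis=0)
        a = a.mean(axis=0)
    if d.shape != a.shape:
        raise ParameterError("channel shapes differ")
    pos = d[d > 0]
    if pos.size == 0:
        raise DegenerateInputError("donor has no positive pixels")
    if np.ptp(pos) > 0:
        fg_mean = pos[pos > threshold_otsu(pos)].mean()
    else:
        fg_mean = pos.mean()
    eps = DONOR_EPS_FRACTION * fg_mean
    corrected = a - alpha * d
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = corrected / d
    undefined = d <= eps
    negative = (corrected < 0) & ~undefined
    ratio[undefined | negative] = np.nan
    return RatioMap(values=ratio, pixel_size_um=pixel_size_um,
                    n_clipped=int(negative.sum()))


def junction_band_mask(cell_mask: np.ndarray, band_width_um: float,
                       pixel_size_um: float) -> np.ndarray:
    """Band of pixels inside the cell within ``band_width_um`` of its edge."""
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ParameterError("cell mask is empty")
    depth = ndimage.distance_transform_edt(cell, sampling=pixel_size_um)
    band = cell & (depth <= band_width_um)
    if not band.any():
        raise DegenerateInputError("empty junction band")
    return band


def junction_rac_map(ratio: RatioMap, cell_mask: np.ndarray,
                     band_width_um: float = 1.0,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Median-split the junction band into high/low Rac1 activity.

    The threshold is the median ratio over the band, so the high class
    covers approximately 50% of the junction.  Returns ``(high_mask,
    band_mask, threshold)``.
    """
    band = junction_band_mask(cell_mask, band_width_um, ratio.pixel_size_um)
    vals = ratio.values[band]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DegenerateInputError("no defined ratio pixels in the band")
    thr = float(np.median(vals))
    high = band & (ratio.values > thr) & ratio.defined
    # tie-break: with discrete values (e.g. a uniform band) the strict
    # comparison can undershoot the ~50% target badly; promote
    # median-valued band pixels in raster order until half the band is high
    target = int(band.sum() // 2)
    deficit = target - int(high.sum())
    if deficit > 0:
        ties = np.argwhere(band & ratio.defined & (ratio.values == thr))
        for r, c in ties[:deficit]:
            high[r, c] = True
    return high, band, thr


def score_site(site_yx: tuple[float, float], high_mask: np.ndarray,
               band_mask: np.ndarray, pixel_size_um: float) -> str:
    """Score a diapedesis site 'high' or 'low' by its nearest band pixel."""
    band_idx = np.argwhere(band_mask)
    if len(band_idx) == 0:
        raise ParameterError("empty band")
    site = np.asarray(site_yx, dtype=np.float64) / pixel_size_um
    nearest = band_idx[np.argmin(((band_idx - site) ** 2).sum(axis=1))]
    return "high" if high_mask[tuple(nearest)] else "low"


def jmp_fret_comparison(ratio: RatioMap, jmp_rois: list[np.ndarray],
                        cell_mask: np.ndarray, band_width_um: float = 3.0,
                        ) -> list[dict]:
    """Paired JMP-ROI mean versus 3 um junction-band mean of the same cell.

    One row per ROI: ``{"roi_id", "jmp_mean", "junction_mean",
    "inside_cell"}``; ROIs that fall outside the cell are flagged rather
    than rejected.
    """
    if not jmp_rois:
        raise ParameterError("need at least one JMP ROI")
    band = junction_band_mask(cell_mask, band_width_um, ratio.pixel_size_um)
    jm = ratio.values[band & ratio.defined]
    if jm.size == 0:
        raise DegenerateInputError("no defined ratio pixels in the band")
    junction_mean = float(jm.mean())
    rows = []
    cell = np.asarray(cell_mask, dtype=bool)
    for i, roi in enumerate(jmp_rois):
        roi = np.asarray(roi, dtype=bool)
        sel = roi & ratio.defined
        if not sel.any():
            raise DegenerateInputError(f"ROI {i} has no defined pixels")
        rows.append({
            "roi_id": i,
            "jmp_mean": float(ratio.values[sel].mean()),
            "junction_mean": junction_mean,
            "inside_cell": bool((roi & cell).sum() == roi.sum()),
        })
    return rows
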