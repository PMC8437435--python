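"""Membrane dynamics maps for 2D time-lapse movies.

A membrane dynamics map assigns to every pixel the temporal coefficient of
variation (CoV = population standard deviation over time divided by the
temporal mean) of a membrane-label movie.  Highly dynamic membrane, such as
junctional membrane protrusions (JMPs), fluctuates strongly in intensity
and lights up in the map.  Because intensity fluctuations also arise from
photobleaching and stage drift, both are corrected before the statistic is
computed.  Analysis is then restricted to a band around the cell-cell
junctions (default half-width 3 um); everything farther away is undefined
(NaN) and the scalar read-out is the mean of the defined band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.registration import phase_cross_correlation

from .containers import DegenerateInputError, ParameterError, TimeLapseStack

__all__ = [
    "DynamicsMap",
    "JunctionBand",
    "preprocess_stack",
    "compute_dynamics_map",
    "apply_junction_band",
    "dynamics_ratio",
    "junction_linescan",
]

#: fraction of the stack's global mean below which a temporal mean is
#: considered too dim to define a CoV
MEAN_EPS_FRACTION = 1e-6


@dataclass
class DynamicsMap:
    """Per-pixel temporal CoV; undefined pixels are NaN."""

    values: np.ndarray
    pixel_size_um: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def summary_mean(self) -> float:
        d = self.defined
        if not d.any():
            raise DegenerateInputError("dynamics map has no defined pixels")
        return float(self.values[d].mean())


@dataclass
class JunctionBand:
    """Binary band of pixels within ``band_halfwidth_um`` of the junction
    skeleton (Euclidean distance in physical units)."""

    mask: np.ndarray
    band_halfwidth_um: float = 3.0


def preprocess_stack(stack: TimeLapseStack, do_bleach: bool = True,
                     do_drift: bool = True,
                     upsample_factor: int = 10,
                     ) -> tuple[TimeLapseStack, np.ndarray]:
    """Correct a movie for photobleaching and rigid drift.

    Bleaching: each frame is divided by its mean over a fixed foreground
    mask (Otsu on the temporal-mean image) and rescaled to the frame-0
    foreground mean, i.e. frame-mean normalization rather than an explicit
    decay fit.  Drift: each frame is registered to frame 0 by
    translation-only phase correlation (subpixel via upsampled cross
    correlation) and shifted back; pixels pulled in from outside become NaN
    so shift-induced borders stay out of the statistics.

    Returns the corrected stack and the per-frame recovered offsets
    (``(T, 2)`` array of (dy, dx), frame 0 is (0, 0)).
    """
    data = stack.data.astype(np.float64).copy()
    t = data.shape[0]
    if t < 2:
        raise ParameterError("need at least 2 frames")
    for i in range(t):
        if not np.any(data[i]):
            raise DegenerateInputError(f"frame {i} is all zero")

    if do_bleach:
        mean_img = data.mean(axis=0)
        if np.ptp(mean_img) > 0:
            fg = mean_img > threshold_otsu(mean_img)
        else:
            fg = np.ones_like(mean_img, dtype=bool)
        if not fg.any():
            fg = np.ones_like(mean_img, dtype=bool)
        means = data[:, fg].mean(axis=1)
        if np.any(means <= 0):
            raise DegenerateInputError("non-positive foreground mean")
        data *= (means[0] / means)[:, None, None]

    offsets = np.zeros((t, 2))
    if do_drift:
        ref = data[0]
        for i in range(1, t):
            shift, _, _ = phase_cross_correlation(
                ref, data[i], upsample_factor=upsample_factor,
                normalization=None)
            offsets[i] = shift
            data[i] = ndimage.shift(data[i], shift, order=1,
                                    mode="constant", cval=np.nan)
    out = stack.copy()
    out.data = data
    return out, offsets


def compute_dynamics_map(stack: TimeLapseStack) -> DynamicsMap:
    """Per-pixel temporal CoV: population sd over T divided by temporal mean.

    Pixels whose temporal mean is at or below a small fraction of the
    global mean, or that contain NaN (e.g. drift borders), are undefined.
    """
    data = stack.data
    if data.shape[0] < 2:
        raise ParameterError("need at least 2 frames for a dynamics map")
    finite = np.all(np.isfinite(data), axis=0)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)  # population flavor, descriptive statistic
    eps = MEAN_EPS_FRACTION * np.nanmean(np.abs(data))
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sd / mean
    cov[~finite | (mean <= eps)] = np.nan
    return DynamicsMap(values=cov, pixel_size_um=stack.pixel_size_um)


def apply_junction_band(dmap: DynamicsMap, junction_mask: np.ndarray,
                        band_halfwidth_um: float = 3.0,
                        normalize_to: float | None = None,
                        ) -> tuple[DynamicsMap, float]:
    """Restrict a dynamics map to the junction band and summarize it.

    The junction mask is skeletonized; pixels farther than
    ``band_halfwidth_um`` (Euclidean, physical units) from the skeleton are
    set undefined.  The summary is the mean over the remaining defined
    pixels, optionally divided by a reference condition's summary
    (``normalize_to``).
    """
    junction_mask = np.asarray(junction_mask, dtype=bool)
    if junction_mask.shape != dmap.values.shape:
        raise ParameterError("mask and map shapes differ")
    if not junction_mask.any():
        raise DegenerateInputError("no junction pixels")
    skel = skeletonize(junction_mask) if junction_mask.sum() > 1 else junction_mask
    if not skel.any():
        skel = junction_mask
    dist = ndimage.distance_transform_edt(~skel, sampling=dmap.pixel_size_um)
    values = dmap.values.copy()
    values[dist > band_halfwidth_um] = np.nan
    masked = DynamicsMap(values=values, pixel_size_um=dmap.pixel_size_um)
    summary = masked.summary_mean()
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ParameterError("normalization reference must be positive")
        summary /= normalize_to
    return masked, summary


def dynamics_ratio(map_a: DynamicsMap, map_b: DynamicsMap,
                   roi: np.ndarray, roi_b: np.ndarray | None = None) -> float:
    """Ratio of the two maps' summary means within regions of interest.

    With one ROI this is the after/before read-out for inhibitor washes
    (same ROI on both maps).  With ``roi_b`` the two maps may be the same
    map compared over two regions, e.g. the two endothelial cells flanking
    an asymmetric JMP.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ParameterError("maps must share geometry")
    roi = np.asarray(roi, dtype=bool)
    roi_b = roi if roi_b is None else np.asarray(roi_b, dtype=bool)
    num = _roi_mean(map_a, roi)
    den = _roi_mean(map_b, roi_b)
    if den <= 0:
        raise DegenerateInputError("denominator summary is not positive")
    return num / den


def _roi_mean(dmap: DynamicsMap, roi: np.ndarray) -> float:
    sel = roi & dmap.defined
    if not sel.any():
        raise DegenerateInputError("ROI contains no defined pixels")
    return float(dmap.values[sel].mean())


def junction_linescan(image: np.ndarray, line: tuple[tuple[float, float],
                                                     tuple[float, float]],
                      width_px: int = 30, n_samples: int | None = None,
                      ) -> tuple[np.ndarray, float, float]:
    """Intensity profile across a junction along a widened line.

    ``image`` may be a z-stack (Z, Y, X); slices are summed first.  The
    line runs perpendicular to the junction; it is widened to ``width_px``
    parallel samples and the profile at each position along the line is the
    mean across the width.  Returns ``(profile, cumulative, per_area)``
    where ``cumulative`` is the summed signal over the whole widened line
    and ``per_area`` is that total normalized by the sampled area (in
    pixel units), i.e. the mean intensity.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.sum(axis=0)
    (y0, x0), (y1, x1) = line
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise ParameterError("zero-length line")
    if width_px < 1:
        raise ParameterError("width_px must be >= 1")
    if n_samples is None:
        n_samples = int(np.ceil(length)) + 1
    u = np.array([y1 - y0, x1 - x0]) / length            # along the line
    nvec = np.array([-u[1], u[0]])                        # across (widening)
    s = np.linspace(0.0, length, n_samples)
    w = (np.arange(width_px) - (width_px - 1) / 2.0)
    yy = y0 + s[:, None] * u[0] + w[None, :] * nvec[0]
    xx = x0 + s[:, None] * u[1] + w[None, :] * nvec[1]
    samples = ndimage.map_coordinates(img, [yy.ravel(), xx.ravel()],
                                      order=1, mode="nearest")
    samples = samples.reshape(n_samples, width_px)
    profile = samples.mean(axis=1)
    cumulative = float(samples.sum())
    per_area = cumulative / samples.size
    return profile, cumulative, per_area
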