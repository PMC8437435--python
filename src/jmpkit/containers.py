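"""Core in-memory containers for the pipeline.

Conventions
-----------
* 2D movies are ``T x Y x X`` float arrays; 3D volumes are ``Z x Y x X``
  (a series is ``T x Z x Y x X``).
* All physical quantities are micrometres; voxel/pixel sizes are attached
  to the containers so downstream geometry is always in physical units.
* 3D coordinates follow the array axis order ``(z, y, x)`` throughout,
  including mesh vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A caller-supplied parameter is out of its documented domain."""


class DegenerateInputError(ValueError):
    """Input data is structurally valid but cannot support the computation."""


@dataclass
class TimeLapseStack:
    """A 2D time-lapse movie with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Intensity values. Negative intensities are not allowed.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    frame_interval_s : float
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 and self.data.ndim != 3:
            raise ParameterError("stack data must be (T, Y, X)")
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "TimeLapseStack":
        return TimeLapseStack(self.data.copy(), self.pixel_size_um,
                              self.frame_interval_s)


@dataclass
class VolumeFrame:
    """One 3D frame with anisotropic voxel calibration.

    ``voxel_size_um`` is ordered ``(z, y, x)`` to match the array axes.
    ``valid_mask`` marks voxels inside the usable (non-padded) region.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_index: int = 0
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError("volume data must be (Z, Y, X)")
        vz, vy, vx = self.voxel_size_um
        if min(vz, vy, vx) <= 0:
            raise ParameterError("voxel sizes must be strictly positive")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape:
                raise ParameterError("valid_mask shape must match data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VolumeSeries:
    """A time series of :class:`VolumeFrame` sharing one calibration."""

    frames: list[VolumeFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].shape
            for f in self.frames:
                if f.shape != shape:
                    raise ParameterError("all frames must share a shape")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> VolumeFrame:
        return self.frames[i]
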