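"""Calibrated raster containers shared across the pipeline.

Two semantic channels run through every stage: "cyan" (the mature-osteoblast
reporter) and "red" (the mature-osteoclast reporter). Containers carry the
physical calibration (µm per pixel / per voxel) alongside the rasters so
that area/volume filters can be expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("cyan", "red")


class ConfigurationError(ValueError):
    """A parameter or config value is invalid; the message names the field."""


class DataError(ValueError):
    """Input data violate a precondition (degenerate image, shape mismatch...)."""


def _as_float_raster(arr, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != ndim:
        raise DataError(f"{name}: expected a {ndim}-D raster, got shape {arr.shape}")
    if arr.size == 0:
        raise DataError(f"{name}: empty raster")
    arr = arr.astype(np.float64, copy=False)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name}: intensities must be finite")
    if arr.min() < 0:
        raise DataError(f"{name}: intensities must be non-negative")
    return arr


@dataclass
class TwoChannelImage:
    """A 2-D two-channel fluorescence image (typically a MIP).

    Attributes
    ----------
    cyan, red
        Intensity rasters of identical shape, finite and non-negative.
    pixel_size_um
        Isotropic in-plane pixel size in µm.
    """

    cyan: np.ndarray
    red: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.cyan = _as_float_raster(self.cyan, "cyan", 2)
        self.red = _as_float_raster(self.red, "red", 2)
        if self.cyan.shape != self.red.shape:
            raise DataError(
                f"channel shape mismatch: cyan {self.cyan.shape} vs red {self.red.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cyan.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ConfigurationError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)


@dataclass
class TwoChannelVolume:
    """A 3-D two-channel stack with anisotropic voxel calibration.

    ``voxel_size_um`` is ordered (dz, dy, dx) to match the (z, y, x) axis
    order of the rasters.
    """

    cyan: np.ndarray
    red: np.ndarray
    voxel_size_um: tuple[float, float, float] = (5.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.cyan = _as_float_raster(self.cyan, "cyan", 3)
        self.red = _as_float_raster(self.red, "red", 3)
        if self.cyan.shape != self.red.shape:
            raise DataError(
                f"channel shape mismatch: cyan {self.cyan.shape} vs red {self.red.shape}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel_size_um must be three positive values (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cyan.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ConfigurationError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)


@dataclass
class TimeLapse:
    """An ordered sequence of two-channel frames at a fixed interval."""

    frames: list[TwoChannelImage] = field(default_factory=list)
    frame_interval_min: float = 8.0

    def __post_init__(self) -> None:
        if not self.frame_interval_min > 0:
            raise ConfigurationError("frame_interval_min must be > 0")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise DataError(f"inconsistent frame shapes: {sorted(shapes)}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def pixel_size_um(self) -> float:
        if not self.frames:
            raise DataError("empty time lapse")
        return self.frames[0].pixel_size_um
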