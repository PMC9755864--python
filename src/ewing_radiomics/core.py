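"""Core containers and errors shared by every pipeline stage.

A :class:`VolumeImage` is a 3D scalar intensity grid with physical voxel
spacing in millimetres; a :class:`RoiMask` is a binary grid aligned to it.
The axial direction is by convention the *third* array axis, so a "slice"
is ``data[:, :, k]`` and in-plane translations act on axes 0 and 1.
Voxel indexing is 0-based with half-open ranges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VolumeImage",
    "RoiMask",
    "DegenerateImageError",
    "EmptyMaskError",
    "InvalidConfigError",
    "InvalidParameterError",
    "PerturbationError",
    "AXIAL_AXIS",
]

#: Array axis indexing axial slices (fixed convention).
AXIAL_AXIS = 2


class DegenerateImageError(ValueError):
    """Raised when an operation requires a non-constant image."""


class EmptyMaskError(ValueError):
    """Raised when a mask has no foreground voxels where one is required."""


class InvalidConfigError(ValueError):
    """Raised for configurations that violate their invariants."""


class InvalidParameterError(ValueError):
    """Raised for out-of-range operation parameters."""


class PerturbationError(RuntimeError):
    """Raised when an ROI perturbation empties the mask."""


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise InvalidConfigError(f"expected 3 per-axis values, got {t!r}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """3D scalar image with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities. Must be finite.
    spacing : 3-tuple of float
        Voxel edge length in mm along each array axis (all > 0).
    origin : 3-tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidConfigError(f"image must be 3D, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacings must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, spacing=None) -> "VolumeImage":
        """Copy of this image carrying new intensities (same geometry unless
        ``spacing`` is given)."""
        return VolumeImage(
            data=data,
            spacing=self.spacing if spacing is None else spacing,
            origin=self.origin,
        )


@dataclass
class RoiMask:
    """Binary region-of-interest grid aligned to a :class:`VolumeImage`.

    ``mode`` distinguishes the whole-tumour 3D ROI from the single-slice 2D
    ROI; in 2D mode every foreground voxel lies in one axial slice.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    mode: str = "3D"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise InvalidConfigError(f"mask must be a 3D grid, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        if self.mode not in ("2D", "3D"):
            raise InvalidConfigError(f"mode must be '2D' or '3D', got {self.mode!r}")
        if self.mode == "2D" and self.data.any():
            slices = np.unique(np.nonzero(self.data)[AXIAL_AXIS])
            if slices.size != 1:
                raise InvalidConfigError("2D mask must occupy exactly one axial slice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if not self.data.any():
            raise EmptyMaskError("mask has no foreground voxels")

    def check_paired(self, image: VolumeImage) -> None:
        """Assert the geometric pairing invariant with ``image``."""
        if self.data.shape != image.data.shape:
            raise InvalidConfigError(
                f"mask shape {self.data.shape} != image shape {image.data.shape}"
            )
        if not np.allclose(self.spacing, image.spacing):
            raise InvalidConfigError(
                f"mask spacing {self.spacing} != image spacing {image.spacing}"
            )

    def with_data(self, data: np.ndarray, mode: str | None = None) -> "RoiMask":
        return RoiMask(data=data, spacing=self.spacing, mode=self.mode if mode is None else mode)
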