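"""Image pre-processing applied before feature extraction.

The stages, in their fixed composition order, are

1. multiplicative bias-field correction (optional, polynomial stand-in),
2. grey-level normalization (z-score over the whole volume),
3. resampling to an isotropic grid (cubic B-spline for the image,
   nearest-neighbour for the mask),
4. Gaussian denoising with a physical-units sigma,

with grey-level discretization (fixed bin *count*) deferred to texture
computation, where the bin edges come from mask-restricted intensities.
2D analysis selects the axial slice with the largest tumour area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    AXIAL_AXIS,
    DegenerateImageError,
    EmptyMaskError,
    InvalidParameterError,
    RoiMask,
    VolumeImage,
)

__all__ = [
    "PreprocessParams",
    "normalize_intensity",
    "resample_isotropic",
    "gaussian_denoise",
    "correct_bias_field",
    "discretize_fixed_bin_count",
    "largest_area_slice",
    "preprocess_case_images",
]


@dataclass
class PreprocessParams:
    """Pre-processing configuration.

    target_spacing : mm, isotropic resampling grid (default 2.0).
    bin_count : number of grey levels for discretization (default 32).
    gaussian_sigma : denoising kernel width in mm (default 1.0; 0 disables).
    normalize : apply whole-volume z-score normalization.
    bias_correction : apply the polynomial bias-field correction stage.
    """

    target_spacing: float = 2.0
    bin_count: int = 32
    gaussian_sigma: float = 1.0
    normalize: bool = True
    bias_correction: bool = False

    def __post_init__(self) -> None:
        if self.bin_count < 2:
            raise InvalidParameterError("bin_count must be >= 2")
        if self.target_spacing <= 0:
            raise InvalidParameterError("target_spacing must be > 0")
        if self.gaussian_sigma < 0:
            raise InvalidParameterError("gaussian_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "target_spacing": self.target_spacing,
            "bin_count": self.bin_count,
            "gaussian_sigma": self.gaussian_sigma,
            "normalize": self.normalize,
            "bias_correction": self.bias_correction,
        }


def normalize_intensity(image: VolumeImage) -> VolumeImage:
    """Z-score the whole volume: output mean 0, standard deviation 1.

    Raises
    ------
    DegenerateImageError
        If the image is constant (zero variance).
    """
    x = np.asarray(image.data, dtype=float)
    sd = float(x.std())
    if sd == 0.0:
        raise DegenerateImageError("cannot normalize a constant image")
    return image.with_data((x - x.mean()) / sd)


def resample_isotropic(
    image: VolumeImage, mask: RoiMask, target_spacing: float = 2.0
) -> tuple[VolumeImage, RoiMask]:
    """Resample image and mask onto a shared isotropic grid.

    The image is interpolated with a cubic B-spline (order 3), the mask with
    nearest-neighbour so it stays binary.
    """
    if target_spacing <= 0:
        raise InvalidParameterError("target_spacing must be > 0")
    mask.check_paired(image)
    factors = tuple(s / target_spacing for s in image.spacing)
    if np.allclose(factors, 1.0):
        out_img = image.with_data(np.asarray(image.data, dtype=float).copy(),
                                  spacing=(target_spacing,) * 3)
        out_mask = RoiMask(mask.data.copy(), spacing=(target_spacing,) * 3, mode=mask.mode)
    else:
        data = ndimage.zoom(np.asarray(image.data, dtype=float), factors,
                            order=3, mode="nearest", grid_mode=True)
        mdata = ndimage.zoom(mask.data.astype(np.uint8), factors,
                             order=0, mode="nearest", grid_mode=True)
        if mdata.shape != data.shape:  # rounding can differ by one voxel
            mdata = _match_shape(mdata, data.shape)
        out_img = VolumeImage(data, spacing=(target_spacing,) * 3, origin=image.origin)
        out_mask = RoiMask(mdata.astype(bool), spacing=(target_spacing,) * 3, mode=mask.mode)
    if not out_mask.data.any():
        raise EmptyMaskError("resampling emptied the mask")
    return out_img, out_mask


def _match_shape(a: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = a
    for ax, (have, want) in enumerate(zip(out.shape, shape)):
        if have > want:
            out = np.take(out, range(want), axis=ax)
        elif have < want:
            pad = [(0, 0)] * out.ndim
            pad[ax] = (0, want - have)
            out = np.pad(out, pad, mode="edge")
    return out


def gaussian_denoise(image: VolumeImage, sigma_mm: float) -> VolumeImage:
    """3D Gaussian smoothing with kernel width given in millimetres.

    ``sigma_mm = 0`` is the identity. The sigma is converted to voxel units
    per axis, so anisotropic grids are smoothed isotropically in physical
    space.
    """
    if sigma_mm < 0:
        raise InvalidParameterError("sigma must be >= 0")
    if sigma_mm == 0:
        return image.with_data(np.asarray(image.data, dtype=float).copy())
    sig_vox = [sigma_mm / s for s in image.spacing]
    return image.with_data(ndimage.gaussian_filter(np.asarray(image.data, dtype=float), sig_vox))


def _poly_design(coords: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of all 3-variable monomials of total degree <= degree."""
    x, y, z = coords.T
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((x ** i) * (y ** j) * (z ** k))
    return np.stack(cols, axis=1)


def correct_bias_field(
    image: VolumeImage, mask: RoiMask, degree: int = 2
) -> tuple[VolumeImage, dict]:
    """Remove a smooth multiplicative intensity inhomogeneity.

    A polynomial of total degree <= ``degree`` is least-squares fitted to the
    log-intensities inside the mask and divided out everywhere; the gain is
    renormalized so the mean intensity inside the mask is preserved. Images
    containing non-positive values are shifted into the positive range first
    (the shift is reported and removed again afterwards).

    Returns the corrected image and a dict with the fitted field (full grid)
    and the applied shift.
    """
    mask.require_nonempty()
    mask.check_paired(image)
    x = np.asarray(image.data, dtype=float)
    shift = 0.0
    mn = float(x.min())
    if mn <= 0:
        shift = -mn + 1e-3 * max(1.0, float(x.max()) - mn)
        x = x + shift
    # physical coordinates scaled to [-1, 1] per axis for conditioning
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in x.shape], indexing="ij"
    )
    coords = np.stack([g.ravel() for g in grids], axis=1)
    inside = mask.data.ravel()
    A = _poly_design(coords[inside], degree)
    logx = np.log(x.ravel()[inside])
    beta, *_ = np.linalg.lstsq(A, logx, rcond=None)
    field_full = np.exp(_poly_design(coords, degree) @ beta).reshape(x.shape)
    corrected = x / field_full
    # renormalize gain so in-mask mean is preserved
    corrected *= x[mask.data].mean() / corrected[mask.data].mean()
    corrected = corrected - shift
    return image.with_data(corrected), {"field": field_full, "shift": shift}


def discretize_fixed_bin_count(values: np.ndarray, bin_count: int) -> np.ndarray:
    """Map intensities to integer grey levels 1..bin_count.

    Bin width is (max - min) / bin_count; level = floor((x - min)/width) + 1,
    with x = max mapped to bin_count. Constant input collapses to level 1
    (degenerate but defined).
    """
    if bin_count < 2:
        raise InvalidParameterError("bin_count must be >= 2")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("need at least one value")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    width = (hi - lo) / bin_count
    levels = np.floor((v - lo) / width).astype(np.int64) + 1
    return np.clip(levels, 1, bin_count)


def largest_area_slice(mask3d: RoiMask) -> tuple[int, RoiMask]:
    """Pick the axial slice with the largest tumour area.

    Ties are broken toward the lowest slice index. Returns the index and a
    single-slice 2D-mode mask on the same grid.
    """
    mask3d.require_nonempty()
    areas = mask3d.data.sum(axis=tuple(ax for ax in range(3) if ax != AXIAL_AXIS))
    idx = int(np.argmax(areas))  # argmax returns the first maximum
    out = np.zeros_like(mask3d.data)
    sl = [slice(None)] * 3
    sl[AXIAL_AXIS] = idx
    out[tuple(sl)] = mask3d.data[tuple(sl)]
    return idx, RoiMask(out, spacing=mask3d.spacing, mode="2D")


def preprocess_case_images(
    images: dict[str, VolumeImage],
    mask: RoiMask,
    params: PreprocessParams,
) -> tuple[dict[str, VolumeImage], RoiMask]:
    """Run the composed pipeline on every sequence of one patient.

    Order: bias correction -> normalization -> resampling -> denoising.
    All sequences share the mask, so the resampled mask of the first sequence
    is reused (the grids are identical by the pairing invariant).
    """
    out_images: dict[str, VolumeImage] = {}
    out_mask: RoiMask | None = None
    for name, img in images.items():
        mask.check_paired(img)
        if params.bias_correction:
            img, _ = correct_bias_field(img, mask)
        if params.normalize:
            img = normalize_intensity(img)
        img, rmask = resample_isotropic(img, mask, params.target_spacing)
        if params.gaussian_sigma > 0:
            img = gaussian_denoise(img, params.gaussian_sigma)
        rmask.check_paired(img)
        out_images[name] = img
        if out_mask is None:
            out_mask = rmask
    assert out_mask is not None
    return out_images, out_mask
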