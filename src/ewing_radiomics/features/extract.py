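"""Feature-vector assembly over sequences, sources and ROI modes.

Canonical feature-name grammar::

    {mode}|{sequence}|{source}|{class}|{name}

e.g. ``3D|T2|wavelet-HLL|glcm|ClusterShade``. Per ROI mode and sequence the
inventory is: 14 shape descriptors (original geometry only) + 93 per source
(18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM), with
sources = original image plus the 8 (3D) or 4 (2D) first-level stationary
wavelet sub-bands — 851 features per sequence in 3D, 479 in 2D.

All texture work happens on the mask bounding box; intensities are
discretized with a fixed bin count over mask voxels, independently per
source image.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ..core import AXIAL_AXIS, EmptyMaskError, InvalidConfigError, RoiMask, VolumeImage
from ..preprocess import PreprocessParams, discretize_fixed_bin_count, largest_area_slice
from . import texture
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .wavelet import DEFAULT_WAVELET, wavelet_decompose

__all__ = [
    "extract_feature_vector",
    "extract_case",
    "compute_sources",
    "parse_feature_name",
    "feature_group",
    "TEXTURE_FAMILIES",
]

TEXTURE_FAMILIES = [
    ("glcm", texture.glcm_features, texture.GLCM_NAMES),
    ("glrlm", texture.glrlm_features, texture.GLRLM_NAMES),
    ("glszm", texture.glszm_features, texture.GLSZM_NAMES),
    ("gldm", texture.gldm_features, texture.GLDM_NAMES),
    ("ngtdm", texture.ngtdm_features, texture.NGTDM_NAMES),
]


def compute_sources(
    array: np.ndarray,
    wavelets: bool = True,
    wavelet_name: str = DEFAULT_WAVELET,
) -> list[tuple[str, np.ndarray]]:
    """Source images for one sequence: the original array and, optionally,
    its stationary wavelet sub-bands (tagged ``wavelet-<LLL..HHH>``)."""
    sources = [("original", np.asarray(array, dtype=float))]
    if wavelets:
        for tag, band in wavelet_decompose(array, wavelet=wavelet_name):
            sources.append((f"wavelet-{tag}", band))
    return sources


def _bbox_slices(mask_nd: np.ndarray) -> tuple[slice, ...]:
    idx = np.nonzero(mask_nd)
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)


def _source_features(
    src: np.ndarray,
    mask_nd: np.ndarray,
    bin_count: int,
    voxel_volume: float,
) -> tuple[OrderedDict, set[str]]:
    """First-order + five texture families for one source array (already
    cropped to the mask bounding box)."""
    values = src[mask_nd]
    q = discretize_fixed_bin_count(values, bin_count)
    levels = np.zeros(mask_nd.shape, dtype=np.int64)
    levels[mask_nd] = q
    out: OrderedDict[str, float] = OrderedDict()
    flags: set[str] = set()
    fo, ffl = first_order_features(values, q, voxel_volume)
    for name in FIRSTORDER_NAMES:
        out[f"firstorder|{name}"] = fo[name]
    flags |= ffl
    for fam, fn, names in TEXTURE_FAMILIES:
        vals, tfl = fn(levels, bin_count)
        for name in names:
            out[f"{fam}|{name}"] = vals[name]
        flags |= tfl
    return out, flags


def extract_feature_vector(
    images: dict[str, VolumeImage],
    mask: RoiMask,
    roi_mode: str,
    params: PreprocessParams | None = None,
    wavelets: bool = True,
    wavelet_name: str = DEFAULT_WAVELET,
    sources_cache: dict[str, list[tuple[str, np.ndarray]]] | None = None,
) -> tuple[OrderedDict, set[str]]:
    """Extract the full named feature vector for one patient and ROI mode.

    Parameters
    ----------
    images : preprocessed sequences, e.g. ``{"T1": ..., "T2": ...}``.
    mask : the ROI; 3D whole-tumour mask, or in 2D mode either the 3D mask
        (largest-area slice is selected here) or an already single-slice
        2D-mode mask.
    roi_mode : "3D" or "2D".
    sources_cache : optional precomputed output of :func:`compute_sources`
        per sequence — reused across ROI perturbations, whose in-plane
        translations never change the source images.

    Returns the ordered name->value mapping and the set of degenerate-value
    flags (each flag is ``<feature context>: <condition>``).
    """
    if roi_mode not in ("2D", "3D"):
        raise InvalidConfigError(f"roi_mode must be '2D' or '3D', got {roi_mode!r}")
    mask.require_nonempty()
    params = params or PreprocessParams()
    bin_count = params.bin_count
    voxel_volume = float(np.prod(mask.spacing))

    if roi_mode == "2D":
        if mask.mode == "3D":
            slice_idx, mask2d = largest_area_slice(mask)
        else:
            mask2d = mask
            slice_idx = int(np.unique(np.nonzero(mask.data)[AXIAL_AXIS])[0])
        mask_nd = np.take(mask2d.data, slice_idx, axis=AXIAL_AXIS)
        shape_mask = mask2d
    else:
        mask_nd = mask.data
        shape_mask = mask

    bbox = _bbox_slices(mask_nd)
    mask_crop = mask_nd[bbox]

    out: OrderedDict[str, float] = OrderedDict()
    all_flags: set[str] = set()
    for seq, img in images.items():
        mask.check_paired(img)
        sh, sfl = shape_features(shape_mask)
        for name in SHAPE_NAMES:
            out[f"{roi_mode}|{seq}|original|shape|{name}"] = sh[name]
        all_flags |= {f"{roi_mode}|{seq}|shape: {f}" for f in sfl}

        arr = img.data
        if roi_mode == "2D":
            arr = np.take(arr, slice_idx, axis=AXIAL_AXIS)
        if sources_cache is not None and seq in sources_cache:
            sources = sources_cache[seq]
        else:
            sources = compute_sources(arr, wavelets=wavelets, wavelet_name=wavelet_name)
            if sources_cache is not None:
                sources_cache[seq] = sources
        for source_tag, src in sources:
            vals, fl = _source_features(src[bbox], mask_crop, bin_count, voxel_volume)
            for key, v in vals.items():
                out[f"{roi_mode}|{seq}|{source_tag}|{key}"] = v
            all_flags |= {f"{roi_mode}|{seq}|{source_tag}: {f}" for f in fl}
    return out, all_flags


def extract_case(case, roi_mode: str, params: PreprocessParams | None = None,
                 wavelets: bool = True, **kw) -> tuple[OrderedDict, set[str]]:
    """Convenience wrapper: extract from a preprocessed PatientCase."""
    return extract_feature_vector(case.images, case.mask3d, roi_mode,
                                  params=params, wavelets=wavelets, **kw)


def parse_feature_name(name: str) -> dict:
    mode, seq, source, cls, base = name.split("|")
    return {"mode": mode, "sequence": seq, "source": source, "class": cls, "name": base}


def feature_group(name: str) -> str:
    """Summary group used in the stability breakdown: shape, first-order,
    textural (original-image texture) or wavelet."""
    parts = parse_feature_name(name)
    if parts["source"].startswith("wavelet"):
        return "wavelet"
    if parts["class"] == "shape":
        return "shape"
    if parts["class"] == "firstorder":
        return "first-order"
    return "textural"
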