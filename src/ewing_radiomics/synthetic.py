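"""Synthetic tumour-MRI cohort generator.

Stands in for a two-centre skeletal Ewing sarcoma cohort (no public
accession exists): ~30 patients, 23 good vs 7 poor responders to
neoadjuvant chemotherapy, two co-registered turbo-spin-echo-like sequences
(T1, T2) with anisotropic native voxel spacing and a blob-like whole-tumour
mask per patient.

Class structure is planted where the downstream selection stage looks for
it: inside the mask, intensities are a Gaussian random field whose *mean
offset* and *spatial correlation length* differ between good and poor
responders by ``class_effect`` (dimensionless, 0 = exchangeable classes).
The mean offset moves first-order statistics (mean, minimum); the
correlation length moves spatial texture (GLCM correlation and cluster
shade, NGTDM strength). T1 and T2 use distinct but correlated field
realizations, plus i.i.d. Gaussian noise and an optional smooth low-order
polynomial multiplicative bias field.

One global seed drives a per-patient ``SeedSequence`` spawn, so cohorts are
bit-reproducible while cases stay mutually independent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .core import InvalidConfigError, RoiMask, VolumeImage

__all__ = [
    "CohortConfig",
    "PatientCase",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "generate_feature_table",
]

GOOD, POOR = "good", "poor"

#: Baseline in-mask intensity parameters (arbitrary MR units).
_BASE_MEAN = {"T1": 100.0, "T2": 150.0}
_FIELD_SD = 10.0
_CORR_LEN_MM = 6.0
_SEQ_CORRELATION = 0.6
_BACKGROUND_MEAN = 60.0
_BACKGROUND_SD = 4.0


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 23 good / 7 poor responders,
    anisotropic native spacing (0.8, 0.8, 4.0) mm that forces a real
    resampling step, tumours 12-20 mm in radius (comfortably above the
    100-voxel floor texture analysis needs).
    """

    n_good: int = 23
    n_poor: int = 7
    grid_shape: tuple[int, int, int] = (64, 64, 28)
    native_spacing: tuple[float, float, float] = (0.8, 0.8, 4.0)
    tumour_radius_range: tuple[float, float] = (12.0, 20.0)
    class_effect: float = 1.0
    noise_sd: float = 5.0
    bias_field_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 1 or self.n_poor < 1:
            raise InvalidConfigError("need at least one patient per class")
        if any(n < 16 for n in self.grid_shape):
            raise InvalidConfigError(f"degenerate grid {self.grid_shape}: every axis needs >= 16 voxels")
        if any(s <= 0 for s in self.native_spacing):
            raise InvalidConfigError("spacings must be positive")
        lo, hi = self.tumour_radius_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("invalid tumour_radius_range")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0 or self.class_effect < 0:
            raise InvalidConfigError("class_effect, noise_sd, bias_field_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_good": self.n_good, "n_poor": self.n_poor,
            "grid_shape": list(self.grid_shape),
            "native_spacing": list(self.native_spacing),
            "tumour_radius_range": list(self.tumour_radius_range),
            "class_effect": self.class_effect, "noise_sd": self.noise_sd,
            "bias_field_amplitude": self.bias_field_amplitude, "seed": self.seed,
        }


@dataclass
class PatientCase:
    patient_id: str
    images: dict[str, VolumeImage]
    mask3d: RoiMask
    label: str  # "good" | "poor"

    def __post_init__(self) -> None:
        if set(self.images) != {"T1", "T2"}:
            raise InvalidConfigError("images must map exactly {T1, T2}")
        if self.label not in (GOOD, POOR):
            raise InvalidConfigError(f"label must be good/poor, got {self.label!r}")
        for img in self.images.values():
            self.mask3d.check_paired(img)
        self.mask3d.require_nonempty()


def _smooth_field(rng: np.random.Generator, shape, spacing, corr_len_mm) -> np.ndarray:
    """Unit-variance Gaussian random field with a physical correlation length."""
    white = rng.standard_normal(shape)
    sig_vox = [corr_len_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sig_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _blob_mask(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Randomized smoothed-ellipsoid tumour mask (largest 6-connected
    component, holes filled, >= 100 voxels)."""
    shape = config.grid_shape
    spacing = np.asarray(config.native_spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing
    lo, hi = config.tumour_radius_range
    for attempt in range(10):
        radii = rng.uniform(lo, hi, size=3)
        # random rotation via QR of a Gaussian matrix
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        centre = extent / 2 + rng.uniform(-0.08, 0.08, size=3) * extent
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
        coords = np.stack([g - c for g, c in zip(grids, centre)], axis=-1)
        rel = coords @ q.T / radii
        quad = (rel ** 2).sum(axis=-1)
        perturb = 0.15 * (attempt < 5) * _smooth_field(rng, shape, spacing, 8.0)
        mask = (quad + perturb) < 1.0
        mask = ndimage.binary_fill_holes(mask)
        lab, n = ndimage.label(mask)  # default structure = 6-connectivity
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
        if mask.sum() >= 100:
            return mask
    raise InvalidConfigError("could not generate a tumour mask with >= 100 voxels")


def _class_params(label: str, class_effect: float) -> tuple[float, float]:
    """(mean offset in intensity units, correlation length in mm)."""
    sign = +0.5 if label == GOOD else -0.5
    mean_off = sign * class_effect * _FIELD_SD
    corr_len = _CORR_LEN_MM * (1.0 + sign * 0.5 * class_effect)
    return mean_off, max(corr_len, 1.0)


def _bias_field(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    """Smooth multiplicative degree-1 polynomial field, mean ~1."""
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    coef = rng.uniform(-1.0, 1.0, size=3)
    lin = sum(c * g for c, g in zip(coef, grids))
    return 1.0 + amplitude * lin / max(np.abs(lin).max(), 1e-12)


def _generate_case(
    patient_id: str, label: str, config: CohortConfig, ss: np.random.SeedSequence
) -> PatientCase:
    rng = np.random.default_rng(ss)
    shape, spacing = config.grid_shape, config.native_spacing
    mask = _blob_mask(rng, config)
    mean_off, corr_len = _class_params(label, config.class_effect)

    shared = _smooth_field(rng, shape, spacing, corr_len)
    background = _BACKGROUND_MEAN + _BACKGROUND_SD * _smooth_field(rng, shape, spacing, 10.0)
    images = {}
    for seq in ("T1", "T2"):
        indep = _smooth_field(rng, shape, spacing, corr_len)
        tex = _SEQ_CORRELATION * shared + np.sqrt(1 - _SEQ_CORRELATION ** 2) * indep
        inside = _BASE_MEAN[seq] + mean_off + _FIELD_SD * tex
        data = np.where(mask, inside, background)
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng.standard_normal(shape)
        if config.bias_field_amplitude > 0:
            data = data * _bias_field(rng, shape, config.bias_field_amplitude)
        images[seq] = VolumeImage(data.astype(np.float32), spacing=spacing)
    return PatientCase(
        patient_id=patient_id,
        images=images,
        mask3d=RoiMask(mask, spacing=spacing, mode="3D"),
        label=label,
    )


def generate_cohort(config: CohortConfig) -> list[PatientCase]:
    """Generate ``n_good + n_poor`` seeded patient cases.

    Identical config (including seed) reproduces the cohort bit-for-bit;
    each patient consumes an independent spawned seed stream.
    """
    n = config.n_good + config.n_poor
    labels = [GOOD] * config.n_good + [POOR] * config.n_poor
    streams = np.random.SeedSequence(config.seed).spawn(n)
    return [
        _generate_case(f"case{i:03d}", lab, config, ss)
        for i, (lab, ss) in enumerate(zip(labels, streams))
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_cohort(cohort: list[PatientCase], directory: str | Path,
                 config: CohortConfig | None = None) -> dict:
    """Write a cohort as NIfTI images + masks, a labels CSV and a JSON
    manifest. Round-trip via :func:`read_cohort` is exact (float32 images,
    uint8 masks)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    rows = []
    for case in cohort:
        entry = {"patient_id": case.patient_id, "label": case.label, "images": {}, "mask": None}
        for seq, img in case.images.items():
            fn = f"{case.patient_id}_{seq}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(img.data, dtype=np.float32),
                                     _affine(img.spacing)), directory / fn)
            entry["images"][seq] = fn
        fn = f"{case.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(case.mask3d.data.astype(np.uint8),
                                 _affine(case.mask3d.spacing)), directory / fn)
        entry["mask"] = fn
        files.append(entry)
        rows.append((case.patient_id, case.label))
    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label"])
        w.writerows(rows)
    manifest = {
        "n_cases": len(cohort),
        "files": files,
        "spacing": list(cohort[0].mask3d.spacing) if cohort else None,
        "axial_axis": 2,
        "config": config.to_dict() if config is not None else None,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory: str | Path) -> list[PatientCase]:
    """Load a cohort written by :func:`write_cohort` (or any directory of
    per-case T1/T2/mask NIfTI files with the same manifest layout)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = {}
    with open(directory / "labels.csv") as fh:
        for row in csv.DictReader(fh):
            labels[row["patient_id"]] = row["label"]
    cohort = []
    for entry in manifest["files"]:
        images = {}
        for seq, fn in entry["images"].items():
            ni = nib.load(directory / fn)
            spacing = tuple(float(v) for v in ni.header.get_zooms()[:3])
            images[seq] = VolumeImage(np.asanyarray(ni.dataobj), spacing=spacing)
        ni = nib.load(directory / entry["mask"])
        spacing = tuple(float(v) for v in ni.header.get_zooms()[:3])
        mask = RoiMask(np.asanyarray(ni.dataobj).astype(bool), spacing=spacing, mode="3D")
        cohort.append(PatientCase(entry["patient_id"], images, mask, labels[entry["patient_id"]]))
    return cohort


# ---------------------------------------------------------------------------
# Feature-level cohort (for selection / classification studies)
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_good: int = 23,
    n_poor: int = 7,
    n_signal: int = 4,
    n_noise: int = 50,
    effect: float = 2.0,
    n_redundant: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Directly simulate a patients x features table with planted effects.

    ``n_signal`` independent features carry a location shift of ``effect``
    (in SD units) between good and poor responders; ``n_noise`` features are
    pure N(0,1) noise; ``n_redundant`` features are near-duplicates (r ~ 1)
    of the first signal features, exercising the collinearity pruner.

    Returns (table, labels, planted feature names). Labels: 1 = good.
    """
    rng = np.random.default_rng(seed)
    n = n_good + n_poor
    y = pd.Series([1] * n_good + [0] * n_poor,
                  index=[f"case{i:03d}" for i in range(n)], name="label")
    cols = {}
    planted = []
    shift = np.where(y.values == 1, effect / 2.0, -effect / 2.0)
    for i in range(n_signal):
        name = f"signal_{i:02d}"
        cols[name] = rng.standard_normal(n) + shift
        planted.append(name)
    for i in range(n_redundant):
        base = cols[planted[i % max(n_signal, 1)]]
        cols[f"redundant_{i:02d}"] = base + 0.05 * rng.standard_normal(n)
    for i in range(n_noise):
        cols[f"noise_{i:03d}"] = rng.standard_normal(n)
    table = pd.DataFrame(cols, index=y.index)
    return table, y, planted
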