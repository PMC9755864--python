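import numpy as np
import pytest

from ewing_radiomics.core import RoiMask, VolumeImage
from ewing_radiomics.preprocess import PreprocessParams, preprocess_case_images
from ewing_radiomics.synthetic import CohortConfig, generate_cohort

#: Small grid used throughout the suite; z-axis >= 16 voxels as required,
#: anisotropic native spacing so resampling is nontrivial.
SMALL_GRID = dict(grid_shape=(40, 40, 16), tumour_radius_range=(10.0, 14.0))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_good=4, n_poor=3, class_effect=2.0, seed=11, **SMALL_GRID)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def preprocessed_case(small_cohort):
    _, cohort = small_cohort
    params = PreprocessParams()
    images, mask = preprocess_case_images(cohort[0].images, cohort[0].mask3d, params)
    return images, mask, params


def random_quantized_roi(rng, ndim=3, max_side=6, n_levels=4):
    """Random quantized ROI: integer levels 1..n_levels with a random mask
    (level 0 outside). Guaranteed at least 2 in-mask voxels."""
    while True:
        shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(ndim))
        levels = rng.integers(1, n_levels + 1, size=shape)
        mask = rng.random(shape) < 0.7
        levels = np.where(mask, levels, 0)
        if (levels > 0).sum() >= 2:
            return levels.astype(np.int64), n_levels


def make_ball_mask(radius_vox, spacing=(1.0, 1.0, 1.0), pad=2):
    n = 2 * radius_vox + 1 + 2 * pad
    c = n // 2
    g = np.indices((n, n, n))
    d2 = sum((g[i] - c) ** 2 for i in range(3))
    return RoiMask(d2 <= radius_vox ** 2, spacing=spacing, mode="3D")
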