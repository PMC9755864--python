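"""Texture-matrix feature families: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All functions operate on a *quantized ROI*: an integer grid of grey levels
1..n_levels with 0 marking voxels outside the mask. The grid may be 3D
(whole-tumour ROI; 13 unique angles, 26-neighbourhood) or 2D (single-slice
ROI; 4 unique angles, 8-neighbourhood). GLCM and GLRLM features are computed
per angle on the normalized matrix and averaged over angles (arithmetic
mean); GLSZM, GLDM and NGTDM are angle-free.

Degenerate limits (single grey level, zero variance) are mapped to the
formula's limit value — e.g. GLCM correlation -> 1, NGTDM strength -> 0 —
and recorded in the accompanying flag set so downstream stages never see
non-finite values unannounced.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "unique_angles",
    "neighbour_offsets",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

_EPS = np.finfo(float).eps


def unique_angles(ndim: int) -> list[tuple[int, ...]]:
    """Distance-1 angle set, one representative per +/- offset pair.

    13 angles in 3D, 4 in 2D.
    """
    offs = []
    for off in np.ndindex(*([3] * ndim)):
        d = tuple(int(o) - 1 for o in off)
        if all(v == 0 for v in d):
            continue
        if tuple(-v for v in d) in offs:
            continue
        offs.append(d)
    return offs


def neighbour_offsets(ndim: int) -> list[tuple[int, ...]]:
    """Full Chebyshev distance-1 neighbourhood (26 in 3D, 8 in 2D)."""
    offs = []
    for off in np.ndindex(*([3] * ndim)):
        d = tuple(int(o) - 1 for o in off)
        if any(v != 0 for v in d):
            offs.append(d)
    return offs


def _shift_slices(shape, off):
    """Slices (a, b) such that arr[a] and arr[b] are the pairs arr[p], arr[p+off]."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, off):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]


def glcm_matrix(levels: np.ndarray, n_levels: int, off) -> np.ndarray:
    """Symmetrized co-occurrence count matrix for a single angle.

    Only pairs with both voxels inside the mask (level > 0) are counted.
    """
    sl_a, sl_b = _shift_slices(levels.shape, off)
    a = levels[sl_a].ravel()
    b = levels[sl_b].ravel()
    valid = (a > 0) & (b > 0)
    P = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    return P + P.T


def _glcm_features_single(P: np.ndarray, flags: set[str]) -> dict[str, float]:
    ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((I * p).sum())
    sigma2 = float((((I - mu) ** 2) * p).sum())

    # difference and sum distributions
    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).ravel() - 2, p.ravel())

    nz = p > 0
    pxnz = px[px > 0]
    hx = float(-(pxnz * np.log2(pxnz)).sum())
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    pxy_outer = np.outer(px, px)
    oz = (pxy_outer > 0) & nz
    hxy1 = float(-(p[oz] * np.log2(pxy_outer[oz])).sum())
    oz2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[oz2] * np.log2(pxy_outer[oz2])).sum())

    da = float((p_diff * k_diff).sum())
    out: dict[str, float] = {}
    out["Autocorrelation"] = float((I * J * p).sum())
    out["JointAverage"] = mu
    cp = I + J - 2 * mu
    out["ClusterProminence"] = float(((cp ** 4) * p).sum())
    out["ClusterShade"] = float(((cp ** 3) * p).sum())
    out["ClusterTendency"] = float(((cp ** 2) * p).sum())
    out["Contrast"] = float((((I - J) ** 2) * p).sum())
    if sigma2 > 0:
        out["Correlation"] = (out["Autocorrelation"] - mu * mu) / sigma2
    else:
        out["Correlation"] = 1.0
        flags.add("glcm.Correlation")
    out["DifferenceAverage"] = da
    pd_nz = p_diff[p_diff > 0]
    out["DifferenceEntropy"] = float(-(pd_nz * np.log2(pd_nz)).sum())
    out["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    out["JointEnergy"] = float((p ** 2).sum())
    out["JointEntropy"] = hxy
    out["Id"] = float((p / (1.0 + np.abs(I - J))).sum())
    out["Idm"] = float((p / (1.0 + (I - J) ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + ((I - J) / ng) ** 2)).sum())
    out["Idn"] = float((p / (1.0 + np.abs(I - J) / ng)).sum())
    iv = (I != J)
    out["InverseVariance"] = float((p[iv] / ((I - J)[iv] ** 2)).sum())
    if hx > 0:
        out["Imc1"] = (hxy - hxy1) / hx
    else:
        out["Imc1"] = 0.0
        flags.add("glcm.Imc1")
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((p_sum * k_sum).sum())
    ps_nz = p_sum[p_sum > 0]
    out["SumEntropy"] = float(-(ps_nz * np.log2(ps_nz)).sum())
    out["SumSquares"] = sigma2
    out["MCC"] = _glcm_mcc(p, px, flags)
    return out


def _glcm_mcc(p: np.ndarray, px: np.ndarray, flags: set[str]) -> float:
    keep = px > 0
    if keep.sum() < 2:
        flags.add("glcm.MCC")
        return 1.0
    psub = p[np.ix_(keep, keep)]
    pxs = px[keep]
    Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
    ev = np.sort(np.linalg.eigvals(Q).real)
    second = max(0.0, float(ev[-2]))
    return float(np.sqrt(second))


def glcm_features(levels: np.ndarray, n_levels: int) -> tuple[dict[str, float], set[str]]:
    """24 GLCM descriptors averaged over the unique distance-1 angles."""
    flags: set[str] = set()
    per_angle = []
    for off in unique_angles(levels.ndim):
        P = glcm_matrix(levels, n_levels, off)
        if P.sum() == 0:
            continue
        per_angle.append(_glcm_features_single(P, flags))
    if not per_angle:
        flags.add("glcm.no_pairs")
        vals = {n: (1.0 if n in ("Correlation", "MCC", "MaximumProbability",
                                 "JointEnergy", "Id", "Idm", "Idmn", "Idn") else 0.0)
                for n in GLCM_NAMES}
        return vals, flags
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLCM_NAMES}, flags


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def glrlm_matrix(levels: np.ndarray, n_levels: int, off) -> np.ndarray:
    """Run-length count matrix R[level-1, length-1] for one direction.

    A run is a maximal string of equal-level in-mask voxels along ``off``.
    """
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum((abs(d) * (n - 1)) ** 2 for d, n in zip(off, shape))))) + 1
    # run starts: in-mask voxels whose predecessor is out of bounds/mask or differs
    pred = np.zeros(shape, dtype=levels.dtype)
    sl_a, sl_b = _shift_slices(shape, off)
    pred[sl_b] = levels[sl_a]  # pred[p] = levels[p - off]
    starts_mask = (levels > 0) & (pred != levels)
    coords = np.argwhere(starts_mask)
    if coords.size == 0:
        return np.zeros((n_levels, 1), dtype=float)
    vals = levels[tuple(coords.T)]
    lengths = np.ones(len(coords), dtype=np.int64)
    cur = coords + np.asarray(off)
    active = np.arange(len(coords))
    while active.size:
        inb = np.all((cur[active] >= 0) & (cur[active] < np.asarray(shape)), axis=1)
        cand = active[inb]
        same = levels[tuple(cur[cand].T)] == vals[cand]
        cont = cand[same]
        lengths[cont] += 1
        cur[cont] += np.asarray(off)
        active = cont
    R = np.zeros((n_levels, int(lengths.max())), dtype=float)
    np.add.at(R, (vals - 1, lengths - 1), 1.0)
    return R


def _weighted_matrix_features(
    M: np.ndarray, n_voxels: int, prefix_names: dict[str, str]
) -> dict[str, float]:
    """Shared feature formulas for GLRLM/GLSZM-style level x size matrices.

    ``prefix_names`` maps canonical roles to family-specific feature names.
    """
    N = M.sum()
    i = np.arange(1, M.shape[0] + 1, dtype=float)
    j = np.arange(1, M.shape[1] + 1, dtype=float)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = M / N
    mu_i = float((I * p).sum())
    mu_j = float((J * p).sum())
    pnz = p[p > 0]
    out = {}
    out[prefix_names["small"]] = float((M / (J ** 2)).sum() / N)
    out[prefix_names["large"]] = float((M * (J ** 2)).sum() / N)
    out[prefix_names["gln"]] = float((M.sum(axis=1) ** 2).sum() / N)
    out[prefix_names["glnn"]] = float((M.sum(axis=1) ** 2).sum() / N ** 2)
    out[prefix_names["sn"]] = float((M.sum(axis=0) ** 2).sum() / N)
    out[prefix_names["snn"]] = float((M.sum(axis=0) ** 2).sum() / N ** 2)
    out[prefix_names["perc"]] = float(N / n_voxels)
    out[prefix_names["glvar"]] = float((((I - mu_i) ** 2) * p).sum())
    out[prefix_names["svar"]] = float((((J - mu_j) ** 2) * p).sum())
    out[prefix_names["entropy"]] = float(-(pnz * np.log2(pnz)).sum())
    out[prefix_names["lgl"]] = float((M / (I ** 2)).sum() / N)
    out[prefix_names["hgl"]] = float((M * (I ** 2)).sum() / N)
    out[prefix_names["slgl"]] = float((M / (I ** 2 * J ** 2)).sum() / N)
    out[prefix_names["shgl"]] = float((M * (I ** 2) / (J ** 2)).sum() / N)
    out[prefix_names["llgl"]] = float((M * (J ** 2) / (I ** 2)).sum() / N)
    out[prefix_names["lhgl"]] = float((M * (I ** 2) * (J ** 2)).sum() / N)
    return out


_GLRLM_ROLES = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "perc": "RunPercentage", "glvar": "GrayLevelVariance", "svar": "RunVariance",
    "entropy": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis", "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis", "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}


def glrlm_features(levels: np.ndarray, n_levels: int) -> tuple[dict[str, float], set[str]]:
    """16 run-length descriptors averaged over the unique angles."""
    flags: set[str] = set()
    n_vox = int((levels > 0).sum())
    per_angle = []
    for off in unique_angles(levels.ndim):
        R = glrlm_matrix(levels, n_levels, off)
        if R.sum() == 0:
            continue
        per_angle.append(_weighted_matrix_features(R, n_vox, _GLRLM_ROLES))
    if not per_angle:
        flags.add("glrlm.no_runs")
        return {n: 0.0 for n in GLRLM_NAMES}, flags
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLRLM_NAMES}, flags


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

_GLSZM_ROLES = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "perc": "ZonePercentage", "glvar": "GrayLevelVariance", "svar": "ZoneVariance",
    "entropy": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis", "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis", "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix S[level-1, size-1].

    Zones are fully connected components (26-connectivity in 3D,
    8-connectivity in 2D) of equal grey level inside the mask.
    """
    structure = np.ones((3,) * levels.ndim, dtype=int)
    sizes_per_level: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            sizes_per_level.append((g, int(s)))
            max_size = max(max_size, int(s))
    S = np.zeros((n_levels, max_size), dtype=float)
    for g, s in sizes_per_level:
        S[g - 1, s - 1] += 1.0
    return S


def glszm_features(levels: np.ndarray, n_levels: int) -> tuple[dict[str, float], set[str]]:
    """16 size-zone descriptors (angle-free)."""
    flags: set[str] = set()
    n_vox = int((levels > 0).sum())
    S = glszm_matrix(levels, n_levels)
    if S.sum() == 0:
        flags.add("glszm.no_zones")
        return {n: 0.0 for n in GLSZM_NAMES}, flags
    return _weighted_matrix_features(S, n_vox, _GLSZM_ROLES), flags


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_NAMES = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix D[level-1, dependence].

    The dependence of a voxel is the number of Chebyshev distance-1
    neighbours inside the mask whose level differs by at most ``alpha``.
    Column j holds dependence j (0-based: j neighbours satisfy the bound).
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in neighbour_offsets(levels.ndim):
        sl_a, sl_b = _shift_slices(levels.shape, off)
        ok = mask[sl_a] & mask[sl_b] & (np.abs(levels[sl_a] - levels[sl_b]) <= alpha)
        dep[sl_a] += ok
    max_dep = int(dep[mask].max()) if mask.any() else 0
    D = np.zeros((n_levels, max_dep + 1), dtype=float)
    np.add.at(D, (levels[mask] - 1, dep[mask]), 1.0)
    return D


def gldm_features(
    levels: np.ndarray, n_levels: int, alpha: int = 0
) -> tuple[dict[str, float], set[str]]:
    """14 dependence descriptors. The size coordinate is dependence + 1."""
    flags: set[str] = set()
    D = gldm_matrix(levels, n_levels, alpha)
    if D.sum() == 0:
        flags.add("gldm.empty")
        return {n: 0.0 for n in GLDM_NAMES}, flags
    N = D.sum()
    i = np.arange(1, D.shape[0] + 1, dtype=float)
    j = np.arange(1, D.shape[1] + 1, dtype=float)  # dependence + 1
    I, J = np.meshgrid(i, j, indexing="ij")
    p = D / N
    mu_i = float((I * p).sum())
    mu_j = float((J * p).sum())
    pnz = p[p > 0]
    out = {
        "SmallDependenceEmphasis": float((D / (J ** 2)).sum() / N),
        "LargeDependenceEmphasis": float((D * (J ** 2)).sum() / N),
        "GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / N),
        "DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / N),
        "DependenceNonUniformityNormalized": float((D.sum(axis=0) ** 2).sum() / N ** 2),
        "GrayLevelVariance": float((((I - mu_i) ** 2) * p).sum()),
        "DependenceVariance": float((((J - mu_j) ** 2) * p).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((D / (I ** 2)).sum() / N),
        "HighGrayLevelEmphasis": float((D * (I ** 2)).sum() / N),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (I ** 2 * J ** 2)).sum() / N),
        "SmallDependenceHighGrayLevelEmphasis": float((D * (I ** 2) / (J ** 2)).sum() / N),
        "LargeDependenceLowGrayLevelEmphasis": float((D * (J ** 2) / (I ** 2)).sum() / N),
        "LargeDependenceHighGrayLevelEmphasis": float((D * (I ** 2) * (J ** 2)).sum() / N),
    }
    return out, flags


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

#: Cap applied to coarseness when the grey-tone difference sum vanishes.
COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and grey-tone difference sums s_i.

    s_i sums |i - mean of in-mask neighbours| over in-mask voxels of level i
    that have at least one in-mask neighbour; voxels without neighbours are
    excluded from both n and s.
    """
    mask = levels > 0
    kernel = np.ones((3,) * levels.ndim, dtype=float)
    kernel[(1,) * levels.ndim] = 0.0
    vals = np.where(mask, levels, 0).astype(float)
    nb_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    nb_cnt = np.rint(nb_cnt)
    has_nb = mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nb_mean = np.where(has_nb, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    n = np.zeros(n_levels, dtype=float)
    s = np.zeros(n_levels, dtype=float)
    lv = levels[has_nb]
    diff = np.abs(levels[has_nb].astype(float) - nb_mean[has_nb])
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, diff)
    return n, s


def ngtdm_features(levels: np.ndarray, n_levels: int) -> tuple[dict[str, float], set[str]]:
    """The five neighbouring grey-tone difference descriptors."""
    flags: set[str] = set()
    n, s = ngtdm_table(levels, n_levels)
    Nv = n.sum()
    if Nv == 0:
        flags.add("ngtdm.empty")
        return {k: 0.0 for k in NGTDM_NAMES}, flags
    p = n / Nv
    i = np.arange(1, n_levels + 1, dtype=float)
    act = p > 0
    ngp = int(act.sum())
    ia, pa, sa = i[act], p[act], s[act]
    out: dict[str, float] = {}

    ps = float((pa * sa).sum())
    if ps > 0:
        out["Coarseness"] = 1.0 / ps
    else:
        out["Coarseness"] = COARSENESS_CAP
        flags.add("ngtdm.Coarseness")

    if ngp > 1:
        pij = np.outer(pa, pa)
        dij = (ia[:, None] - ia[None, :]) ** 2
        out["Contrast"] = float((pij * dij).sum() / (ngp * (ngp - 1)) * s.sum() / Nv)
        denom = np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :]).sum()
        out["Busyness"] = float(ps / denom) if denom > 0 else 0.0
        adiff = np.abs(ia[:, None] - ia[None, :])
        out["Complexity"] = float(
            (adiff * (pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :])
             / (pa[:, None] + pa[None, :])).sum() / Nv
        )
        ssum = s.sum()
        if ssum > 0:
            out["Strength"] = float(
                ((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2).sum() / ssum
            )
        else:
            out["Strength"] = 0.0
            flags.add("ngtdm.Strength")
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
        flags.add("ngtdm.single_level")
    return out, flags
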