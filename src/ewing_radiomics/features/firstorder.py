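"""First-order (intensity histogram) descriptors.

Eighteen statistics of the in-ROI intensity distribution. Entropy and
uniformity are computed on the fixed-bin-count quantized values; everything
else on the raw intensities. Degenerate inputs (zero variance) set skewness
and kurtosis to 0 and flag the case rather than emitting NaN.
"""

from __future__ import annotations

import numpy as np

from ..core import EmptyMaskError

__all__ = ["first_order_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
]


def first_order_features(
    values: np.ndarray,
    quantized: np.ndarray,
    voxel_volume: float,
) -> tuple[dict[str, float], set[str]]:
    """Compute the 18 first-order descriptors.

    Parameters
    ----------
    values : raw in-ROI intensities (1D).
    quantized : matching integer grey levels (1..n_bins), used for entropy
        and uniformity.
    voxel_volume : physical voxel volume in mm^3 (for total energy).

    Kurtosis is the raw fourth standardized moment (not excess).
    Skewness/kurtosis use population (biased) moments.
    """
    x = np.asarray(values, dtype=float).ravel()
    q = np.asarray(quantized).ravel()
    if x.size == 0:
        raise EmptyMaskError("empty ROI")
    flags: set[str] = set()
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p50, p75, p90 = (float(np.percentile(x, p)) for p in (10, 25, 50, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    counts = np.bincount(q)[1:].astype(float)
    p_hist = counts[counts > 0] / q.size

    out = {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float((x ** 2).sum() * voxel_volume),
        "Entropy": float(-(p_hist * np.log2(p_hist)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Variance": var,
        "Uniformity": float((p_hist ** 2).sum()),
    }
    if var > 0:
        sd = np.sqrt(var)
        out["Skewness"] = float(((x - mean) ** 3).mean() / sd ** 3)
        out["Kurtosis"] = float(((x - mean) ** 4).mean() / sd ** 4)
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
        flags.add("firstorder.moments")
    return out, flags
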