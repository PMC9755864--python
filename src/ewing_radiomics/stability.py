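"""ROI-translation reproducibility analysis.

Multiple manual tumour delineations are mimicked by translating the ROI in
the positive and negative in-plane directions (array axes 0 and 1) by 10%
of the tumour bounding-box length (whole voxels, minimum 1). Features are
extracted from the original and the 4 translated ROIs, and per-feature
agreement over the five variants is quantified with the intraclass
correlation coefficient ICC(2,1) — two-way random effects, absolute
agreement, single measurement. Features with ICC > 0.75 (strict) are
called stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EmptyMaskError, InvalidParameterError, PerturbationError, RoiMask
from .features.extract import feature_group

__all__ = [
    "bounding_box",
    "translate_roi",
    "build_perturbation_set",
    "PerturbationSet",
    "icc_two_way_random",
    "icc_three_way_mixed",
    "stability_filter",
    "stable_fraction_summary",
    "compare_stability",
    "DEFAULT_ICC_THRESHOLD",
    "TRANSLATION_FRACTION",
]

DEFAULT_ICC_THRESHOLD = 0.75
TRANSLATION_FRACTION = 0.10
_AXES = {"x": 0, "y": 1}


def bounding_box(mask: RoiMask) -> list[tuple[int, int]]:
    """Tight per-axis half-open index ranges of the mask foreground."""
    mask.require_nonempty()
    idx = np.nonzero(mask.data)
    return [(int(a.min()), int(a.max()) + 1) for a in idx]


def translate_roi(
    mask: RoiMask, axis: str, sign: int, fraction: float = TRANSLATION_FRACTION
) -> RoiMask:
    """Shift the mask along ``axis`` ('x' -> array axis 0, 'y' -> axis 1).

    The shift is ``max(1, round(fraction * bounding-box length))`` whole
    voxels; voxels pushed outside the grid are dropped. Raises
    :class:`PerturbationError` if the translation empties the mask.
    """
    if axis not in _AXES:
        raise InvalidParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    if sign not in (+1, -1):
        raise InvalidParameterError("sign must be +1 or -1")
    ax = _AXES[axis]
    box = bounding_box(mask)
    length = box[ax][1] - box[ax][0]
    shift = max(1, round(fraction * length)) * sign
    out = np.roll(mask.data, shift, axis=ax)
    # voxels wrapped around by roll are dropped, not reintroduced
    sl = [slice(None)] * 3
    if shift > 0:
        sl[ax] = slice(0, shift)
    else:
        sl[ax] = slice(shift, None)
    out[tuple(sl)] = False
    if not out.any():
        raise PerturbationError(f"translation {axis}{'+' if sign > 0 else '-'} emptied the mask")
    return mask.with_data(out)


@dataclass
class PerturbationSet:
    """The original ROI plus its four in-plane translations."""

    original: RoiMask
    translated: dict[str, RoiMask]  # keys x+, x-, y+, y-

    @property
    def masks(self) -> list[RoiMask]:
        return [self.original] + [self.translated[k] for k in ("x+", "x-", "y+", "y-")]

    @property
    def variant_names(self) -> list[str]:
        return ["original", "x+", "x-", "y+", "y-"]


def build_perturbation_set(mask: RoiMask, fraction: float = TRANSLATION_FRACTION) -> PerturbationSet:
    """Original + 4 translated ROIs (x+/-, y+/-) at the given fraction."""
    mask.require_nonempty()
    translated = {
        f"{axis}{'+' if sign > 0 else '-'}": translate_roi(mask, axis, sign, fraction)
        for axis in ("x", "y")
        for sign in (+1, -1)
    }
    return PerturbationSet(original=mask, translated=translated)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _two_way_anova(ratings: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares (rows=subjects, columns=raters): MSR, MSC, MSE."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidParameterError("need an n>=2 by k>=2 ratings matrix")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("ratings must be finite")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way_random(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``. Returns NaN
    (undefined) when the total variance is zero — the caller treats that as
    unstable.
    """
    msr, msc, mse, n, k = _two_way_anova(ratings)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        return float("nan")
    return float((msr - mse) / denom)


def icc_three_way_mixed(ratings: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single rater —
    ``(MSR - MSE) / (MSR + (k-1) MSE)``. Offered as the configurable
    alternative agreement model."""
    msr, _msc, mse, _n, k = _two_way_anova(ratings)
    denom = msr + (k - 1) * mse
    if abs(denom) < 1e-300:
        return float("nan")
    return float((msr - mse) / denom)


_ICC_MODELS = {"icc2": icc_two_way_random, "icc3": icc_three_way_mixed}


def stability_filter(
    tables: list[pd.DataFrame],
    threshold: float = DEFAULT_ICC_THRESHOLD,
    icc_model: str = "icc2",
) -> pd.DataFrame:
    """Per-feature ICC over aligned per-ROI-variant feature tables.

    ``tables`` holds one patients x features frame per ROI variant (5 for
    the standard perturbation set), all with identical index and columns.
    Returns a frame indexed by feature with columns ``icc``, ``stable``
    (strict ``icc > threshold``; undefined ICC counts as unstable) and the
    summary ``group`` parsed from the canonical name grammar (generic
    column names fall back to group 'other').
    """
    if len(tables) < 2:
        raise InvalidParameterError("need at least 2 ROI-variant tables")
    first = tables[0]
    for t in tables[1:]:
        if not (t.index.equals(first.index) and t.columns.equals(first.columns)):
            raise InvalidParameterError("tables must share patients and features")
    icc_fn = _ICC_MODELS[icc_model]
    rows = []
    stacked = np.stack([t.values for t in tables], axis=2)  # n x p x k
    for j, feat in enumerate(first.columns):
        ratings = stacked[:, j, :]
        if not np.all(np.isfinite(ratings)):
            icc = float("nan")
        else:
            icc = icc_fn(ratings)
        stable = bool(np.isfinite(icc) and icc > threshold)
        try:
            group = feature_group(feat)
        except ValueError:
            group = "other"
        rows.append({"feature": feat, "group": group, "icc": icc, "stable": stable})
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["icc_model"] = icc_model
    out.attrs["threshold"] = threshold
    return out


def stable_fraction_summary(icc_table: pd.DataFrame) -> pd.DataFrame:
    """Stable-feature fractions overall and per summary group."""
    rows = [{
        "group": "all",
        "n_features": len(icc_table),
        "n_stable": int(icc_table["stable"].sum()),
        "stable_fraction": float(icc_table["stable"].mean()) if len(icc_table) else float("nan"),
    }]
    for group, sub in icc_table.groupby("group", sort=True):
        rows.append({
            "group": group,
            "n_features": len(sub),
            "n_stable": int(sub["stable"].sum()),
            "stable_fraction": float(sub["stable"].mean()),
        })
    return pd.DataFrame(rows)


def compare_stability(icc_a: pd.DataFrame, icc_b: pd.DataFrame) -> dict:
    """Welch two-sample t-test between two ICC value distributions
    (e.g. 3D vs 2D). Returns t, degrees of freedom and the two-sided p."""
    a = np.asarray(icc_a["icc"] if isinstance(icc_a, pd.DataFrame) else icc_a, dtype=float)
    b = np.asarray(icc_b["icc"] if isinstance(icc_b, pd.DataFrame) else icc_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("need >= 2 finite ICC values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb > 0:
        dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        dof = float(len(a) + len(b) - 2)
    return {"t": float(res.statistic), "dof": float(dof), "p": float(res.pvalue)}
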