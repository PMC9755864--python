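"""Feature selection: collinearity pruning then rank-sum significance.

Among the ICC-stable features, redundant ones are removed by iterative
Pearson-correlation pruning (|r| > 0.8: of the offending pair, drop the
member with the higher mean |r| to all surviving features). The survivors
are then tested for class discrimination with the two-sided Wilcoxon
rank-sum test; features with p < 0.05 are kept and ranked by p. No
multiple-testing correction is applied (reported explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidParameterError

__all__ = [
    "collinearity_prune",
    "wilcoxon_select",
    "SelectionResult",
    "select_features",
    "DEFAULT_R_THRESHOLD",
    "DEFAULT_ALPHA",
]

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_ALPHA = 0.05


def collinearity_prune(
    table: pd.DataFrame, r_threshold: float = DEFAULT_R_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Iteratively remove one member of every highly collinear pair.

    While any surviving pair has |r| > ``r_threshold``, take the
    highest-|r| pair and drop the member with the larger mean |r| against
    all currently surviving features (ties broken by dropping the
    lexicographically later name). Zero-variance features are removed
    first and flagged.

    Returns (survivors in original column order, degenerate feature names).
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise InvalidParameterError("need >= 2 features over >= 3 patients")
    degenerate = [c for c in table.columns if table[c].std() == 0]
    cols = [c for c in table.columns if c not in degenerate]
    if len(cols) < 2:
        return cols, degenerate
    corr = np.abs(np.corrcoef(table[cols].values, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), corr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_threshold:
            break
        mean_i = sub[i, alive].sum() / max(alive.sum() - 1, 1)
        mean_j = sub[j, alive].sum() / max(alive.sum() - 1, 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # tie: lexicographically later canonical name goes
            drop = i if cols[i] > cols[j] else j
        alive[drop] = False
    survivors = [c for c, a in zip(cols, alive) if a]
    return survivors, degenerate


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 10 members and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = (len(x) <= 10 and len(y) <= 10) and not ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.pvalue)


@dataclass
class SelectionResult:
    """Outcome of the collinearity + significance chain."""

    survivors: list[str]                #: features surviving collinearity pruning
    selected: pd.DataFrame              #: final features with p-values, p ascending
    degenerate: list[str]
    r_threshold: float = DEFAULT_R_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    top_k: int | None = None
    #: no multiple-testing correction is applied to the rank-sum p-values
    multiple_testing_correction: str = "none"

    @property
    def selected_features(self) -> list[str]:
        return list(self.selected.index)


def wilcoxon_select(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank-sum significance ranking of each feature.

    Returns the features with p < ``alpha`` sorted by ascending p (the full
    ranking if none pass and ``top_k`` is set, truncated to ``top_k``).
    Labels: 1/"good" = good responder, 0/"poor" = poor responder.
    """
    y = _binary_labels(labels, table.index)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise InvalidParameterError("need >= 2 patients in each response class")
    ps = {}
    for feat in table.columns:
        v = table[feat].values.astype(float)
        ps[feat] = _rank_sum_p(v[y == 1], v[y == 0])
    out = pd.Series(ps, name="p").sort_values(kind="mergesort").to_frame()
    kept = out[out["p"] < alpha]
    if top_k is not None:
        if len(kept) < top_k:
            kept = out.head(top_k)
        else:
            kept = kept.head(top_k)
    return kept


def select_features(
    table: pd.DataFrame,
    labels: pd.Series,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    top_k: int | None = None,
) -> SelectionResult:
    """Run the full chain: collinearity pruning then rank-sum selection."""
    survivors, degenerate = collinearity_prune(table, r_threshold)
    selected = wilcoxon_select(table[survivors], labels, alpha=alpha, top_k=top_k)
    return SelectionResult(
        survivors=survivors,
        selected=selected,
        degenerate=degenerate,
        r_threshold=r_threshold,
        alpha=alpha,
        top_k=top_k,
    )


def _binary_labels(labels: pd.Series, index) -> np.ndarray:
    s = labels.reindex(index) if isinstance(labels, pd.Series) else pd.Series(labels, index=index)
    if s.isna().any():
        raise InvalidParameterError("labels missing for some patients")
    vals = s.values
    if vals.dtype.kind in "OUS":
        return np.asarray([1 if v == "good" else 0 for v in vals])
    return vals.astype(int)
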