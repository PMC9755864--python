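"""SMOTE-balanced response classification under repeated 80-20 hold-out.

Three classifiers — 1-nearest-neighbour (Euclidean, unweighted), logistic
regression and a 100-tree random forest — are trained on the selected
features and evaluated over 100 stratified 80-20 hold-out repeats. Inside
every training partition (never the test set) the minority class is
oversampled to parity with SMOTE; features are standardized with train-set
statistics. Score-returning classifiers (LR, RF) are binarized at the
threshold maximizing balanced accuracy on the training scores, applied
unchanged to the test set. The positive class is the *good responder*.

The split plan is a function of the labels and the seed only, so 2D and 3D
analyses of the same cohort share identical partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier

from .core import InvalidConfigError, InvalidParameterError

__all__ = [
    "SplitPlan",
    "make_split_plan",
    "smote_oversample",
    "balance_training_set",
    "train_classifier",
    "select_threshold",
    "evaluate_split",
    "per_patient_rate",
    "run_classification",
    "EvalReport",
    "CLASSIFIERS",
    "METRICS",
    "RATE_THRESHOLD",
]

CLASSIFIERS = ("knn", "logreg", "rf")
METRICS = ("specificity", "sensitivity", "balanced_accuracy", "auc", "accuracy", "precision")
#: Per-patient correct-classification rate cut-off ("at least 80% of times").
RATE_THRESHOLD = 0.80
SMOTE_K = 5


@dataclass
class SplitPlan:
    """Repeated hold-out partitions of patient ids."""

    splits: list[tuple[np.ndarray, np.ndarray]]  # (train ids, test ids)
    seed: int
    train_fraction: float
    stratified: bool

    def __len__(self) -> int:
        return len(self.splits)


def make_split_plan(
    labels: pd.Series,
    train_fraction: float = 0.8,
    repeats: int = 100,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Seeded (stratified) 80-20 hold-out plan over patient ids.

    Stratification preserves the class ratio to the nearest integer and
    guarantees at least one member of each class in every test set.
    """
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    y = _to_binary(labels)
    ids = np.asarray(labels.index)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise InvalidConfigError("need >= 2 patients per class")
    test_size = 1.0 - train_fraction
    if stratified:
        n_test = int(round(test_size * len(ids)))
        if min(counts) * test_size < 0.5 and n_test < 2:
            raise InvalidConfigError("class too small to appear in stratified test sets")
        splitter = StratifiedShuffleSplit(
            n_splits=repeats, test_size=test_size, random_state=seed
        )
        splits = [(ids[tr], ids[te]) for tr, te in splitter.split(np.zeros(len(ids)), y)]
    else:
        rng = np.random.default_rng(seed)
        n_test = max(1, int(round(test_size * len(ids))))
        splits = []
        for _ in range(repeats):
            perm = rng.permutation(len(ids))
            splits.append((ids[perm[n_test:]], ids[perm[:n_test]]))
    return SplitPlan(splits=splits, seed=seed, train_fraction=train_fraction,
                     stratified=stratified)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    minority: np.ndarray,
    n_synthetic: int,
    k_neighbours: int = SMOTE_K,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic minority samples: ``x + u (x_nn - x)``, u ~ U[0, 1].

    ``x`` is a random minority sample and ``x_nn`` one of its k nearest
    minority neighbours (Euclidean); k is capped at minority size - 1.
    Refuses minorities of size < 2 (no direction to interpolate along).
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise InvalidParameterError("SMOTE needs a minority of >= 2 samples")
    if n_synthetic <= 0:
        return np.empty((0, X.shape[1]))
    rng = rng or np.random.default_rng()
    k = min(k_neighbours, len(X) - 1)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, len(X), size=n_synthetic)
    pick = rng.integers(0, k, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    neigh = X[nn_idx[base, pick]]
    return X[base] + u[:, None] * (neigh - X[base])


def balance_training_set(
    X: np.ndarray, y: np.ndarray, k_neighbours: int = SMOTE_K,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by SMOTE-oversampling the minority class."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return np.asarray(X, dtype=float), y
    minority_label = int(np.argmin(counts))
    n_syn = int(abs(counts[1] - counts[0]))
    syn = smote_oversample(np.asarray(X)[y == minority_label], n_syn,
                           k_neighbours=k_neighbours, rng=rng)
    Xb = np.vstack([X, syn])
    yb = np.concatenate([y, np.full(n_syn, minority_label)])
    return Xb, yb


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def train_classifier(name: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit one of the three study classifiers on a (balanced, standardized)
    training set. Non-finite inputs are rejected."""
    X_train = np.asarray(X_train, dtype=float)
    if not np.all(np.isfinite(X_train)):
        raise InvalidParameterError("non-finite features in training data")
    if name == "knn":
        model = KNeighborsClassifier(n_neighbors=1, weights="uniform", metric="euclidean")
        model.fit(X_train, y_train)
        return model
    if name == "logreg":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegression(penalty=None, max_iter=2000)
            model.fit(X_train, y_train)
            if np.max(np.abs(model.coef_)) > 1e4 or model.n_iter_[0] >= 2000:
                # (quasi-)separation: fall back to weak L2 regularization
                model = LogisticRegression(penalty="l2", C=100.0, max_iter=2000)
                model.fit(X_train, y_train)
                model.separation_fallback_ = True
        return model
    if name == "rf":
        model = RandomForestClassifier(n_estimators=100, max_features="sqrt", random_state=seed)
        model.fit(X_train, y_train)
        return model
    raise InvalidParameterError(f"unknown classifier {name!r}")


def _scores(model, X) -> np.ndarray | None:
    """Positive-class score, or None for hard-label classifiers (1-NN)."""
    if isinstance(model, KNeighborsClassifier):
        return None
    proba = model.predict_proba(np.asarray(X, dtype=float))
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, pos_col]


def select_threshold(scores_train: np.ndarray, y_train: np.ndarray) -> float:
    """Binarization threshold maximizing balanced accuracy on the training
    scores; ties resolve to the lowest threshold. Constant scores fall back
    to 0.5 (degenerate)."""
    s = np.asarray(scores_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    uniq = np.unique(s)
    if len(uniq) == 1:
        return 0.5
    # candidate thresholds: below the minimum, then midpoints of sorted
    # unique scores (prediction = score >= threshold)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_ba = cands[0], -1.0
    n_pos = max((y == 1).sum(), 1)
    n_neg = max((y == 0).sum(), 1)
    for t in cands:
        pred = (s >= t).astype(int)
        sens = ((pred == 1) & (y == 1)).sum() / n_pos
        spec = ((pred == 0) & (y == 0)).sum() / n_neg
        ba = (sens + spec) / 2.0
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, t
    return float(best_t)


def evaluate_split(
    predictions: np.ndarray, scores: np.ndarray | None, y_test: np.ndarray
) -> dict[str, float]:
    """Confusion-matrix metric panel for one repeat.

    Positive class = good responder (label 1). AUC uses the rank statistic
    over test scores; hard-label classifiers get the two-point-ROC AUC from
    their 0/1 predictions. Single-class test sets leave the undefined
    entries as NaN (excluded from that metric's average).
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(y_test, dtype=int)
    if len(pred) != len(y):
        raise InvalidParameterError("predictions and truth differ in length")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    acc = (tp + tn) / len(y)
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, scores if scores is not None else pred))
    else:
        auc = float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "auc": auc,
        "accuracy": acc,
        "precision": prec,
    }


def per_patient_rate(records: pd.DataFrame, threshold: float = RATE_THRESHOLD) -> pd.DataFrame:
    """Per-patient correct-classification rates over test-set appearances.

    ``records`` has one row per (classifier, repeat, patient) test
    prediction, columns ``classifier``, ``patient_id``, ``correct``.
    Returns patients x classifiers rate table plus an ``all_classifiers``
    column marking patients at or above the threshold for *every*
    classifier (the threshold is inclusive).
    """
    rates = (
        records.groupby(["patient_id", "classifier"])["correct"].mean().unstack("classifier")
    )
    rates["all_classifiers"] = (rates >= threshold).all(axis=1)
    return rates


@dataclass
class EvalReport:
    """Metric panel (mean +/- SD over repeats) and per-patient rates."""

    metrics: pd.DataFrame          #: rows metric, columns classifier, cells mean
    metrics_sd: pd.DataFrame
    per_repeat: pd.DataFrame       #: long form, one row per (classifier, repeat)
    patient_rates: pd.DataFrame
    rate_threshold: float = RATE_THRESHOLD
    positive_class: str = "good"

    def n_patients_at_threshold(self, classifier: str) -> int:
        return int((self.patient_rates[classifier] >= self.rate_threshold).sum())

    @property
    def n_patients_all_classifiers(self) -> int:
        return int(self.patient_rates["all_classifiers"].sum())

    def table(self) -> pd.DataFrame:
        """'mean +/- SD' presentation table (metric x classifier)."""
        disp = self.metrics.copy().astype(object)
        for m in disp.index:
            for c in disp.columns:
                disp.loc[m, c] = f"{self.metrics.loc[m, c]:.2f} ± {self.metrics_sd.loc[m, c]:.2f}"
        return disp


def run_classification(
    table: pd.DataFrame,
    labels: pd.Series,
    plan: SplitPlan,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    smote_k: int = SMOTE_K,
    seed: int = 0,
) -> EvalReport:
    """Evaluate the classifier panel on a feature table under a split plan.

    Per repeat: standardize with train statistics, SMOTE-balance the
    training partition, fit each classifier, binarize scores at the
    train-selected threshold, score the untouched test set.
    """
    y_all = pd.Series(_to_binary(labels), index=labels.index)
    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(len(plan.splits))
    rows = []
    records = []
    for r, ((train_ids, test_ids), ss) in enumerate(zip(plan.splits, repeat_seeds)):
        Xtr = table.loc[train_ids].values.astype(float)
        Xte = table.loc[test_ids].values.astype(float)
        ytr = y_all.loc[train_ids].values
        yte = y_all.loc[test_ids].values
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        rng = np.random.default_rng(ss)
        Xb, yb = balance_training_set(Xtr, ytr, k_neighbours=smote_k, rng=rng)
        clf_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        for name in classifiers:
            model = train_classifier(name, Xb, yb, seed=clf_seed)
            scores_te = _scores(model, Xte)
            if scores_te is None:
                pred = model.predict(Xte).astype(int)
            else:
                thr = select_threshold(_scores(model, Xb), yb)
                pred = (scores_te >= thr).astype(int)
            m = evaluate_split(pred, scores_te, yte)
            m.update({"classifier": name, "repeat": r})
            rows.append(m)
            for pid, p, t in zip(test_ids, pred, yte):
                records.append({"classifier": name, "repeat": r,
                                "patient_id": pid, "correct": bool(p == t)})
    per_repeat = pd.DataFrame(rows)
    mean_tbl = per_repeat.groupby("classifier")[list(METRICS)].mean().T
    sd_tbl = per_repeat.groupby("classifier")[list(METRICS)].std(ddof=1).T
    rates = per_patient_rate(pd.DataFrame(records))
    return EvalReport(metrics=mean_tbl, metrics_sd=sd_tbl, per_repeat=per_repeat,
                      patient_rates=rates)


def _to_binary(labels: pd.Series | np.ndarray) -> np.ndarray:
    vals = labels.values if isinstance(labels, pd.Series) else np.asarray(labels)
    if vals.dtype.kind in "OUS":
        return np.asarray([1 if v == "good" else 0 for v in vals])
    return vals.astype(int)
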