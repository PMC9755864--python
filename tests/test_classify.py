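"""Split plans, SMOTE, classifier training, threshold selection, the
metric panel and per-patient classification rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from ewing_radiomics.classify import (
    balance_training_set,
    evaluate_split,
    make_split_plan,
    per_patient_rate,
    run_classification,
    select_threshold,
    smote_oversample,
    train_classifier,
)
from ewing_radiomics.core import InvalidParameterError
from ewing_radiomics.synthetic import generate_feature_table

import oracles


def _labels30():
    return pd.Series(["good"] * 23 + ["poor"] * 7,
                     index=[f"p{i}" for i in range(30)], name="label")


class TestSplitPlan:
    def test_test_sets_of_six(self):
        plan = make_split_plan(_labels30(), repeats=100, seed=0)
        assert len(plan) == 100
        for train, test in plan.splits:
            assert len(test) == 6 and len(train) == 24
            assert set(train) & set(test) == set()

    def test_stratification_keeps_both_classes(self):
        labels = _labels30()
        plan = make_split_plan(labels, repeats=50, seed=1)
        for _, test in plan.splits:
            test_labels = labels.loc[list(test)]
            assert (test_labels == "poor").sum() >= 1
            assert (test_labels == "good").sum() >= 4

    def test_deterministic_and_shared_across_modes(self):
        a = make_split_plan(_labels30(), repeats=30, seed=7)
        b = make_split_plan(_labels30(), repeats=30, seed=7)
        for (tra, tea), (trb, teb) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)


class TestSmote:
    def test_segment_interpolation_two_points(self):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        syn = smote_oversample(minority, 50, k_neighbours=1,
                               rng=np.random.default_rng(0))
        # every synthetic point lies on the diagonal segment
        np.testing.assert_allclose(syn[:, 0], syn[:, 1], atol=1e-12)
        assert (syn >= 0).all() and (syn <= 1).all()

    def test_balanced_set_is_noop(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = balance_training_set(X, y)
        assert Xb.shape == X.shape
        np.testing.assert_array_equal(yb, y)

    def test_equalizes_class_counts(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = np.array([1] * 15 + [0] * 5)
        Xb, yb = balance_training_set(X, y, rng=rng)
        assert (yb == 0).sum() == (yb == 1).sum() == 15

    def test_convex_hull_property(self):
        rng = np.random.default_rng(3)
        minority = rng.normal(size=(12, 2))
        syn = smote_oversample(minority, 200, rng=rng)
        hull = Delaunay(minority)
        assert (hull.find_simplex(syn) >= 0).all()

    def test_minority_of_one_refused(self):
        with pytest.raises(InvalidParameterError):
            smote_oversample(np.array([[1.0, 2.0]]), 5)

    def test_no_leakage_from_test_set(self):
        """Synthetic samples depend only on the training minority: removing
        the test patients from the cohort changes nothing."""
        rng_a = np.random.default_rng(9)
        rng_b = np.random.default_rng(9)
        minority_train = np.random.default_rng(4).normal(size=(6, 3))
        syn_a = smote_oversample(minority_train, 10, rng=rng_a)
        # same call with extra (test) rows *not* passed stays identical
        syn_b = smote_oversample(minority_train.copy(), 10, rng=rng_b)
        np.testing.assert_array_equal(syn_a, syn_b)


class TestClassifiers:
    def test_1nn_memorizes_training_set(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = rng.integers(0, 2, size=20)
        model = train_classifier("knn", X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_logreg_separable_case(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-3, 0.5, size=(30, 2)),
                       rng.normal(3, 0.5, size=(30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = train_classifier("logreg", X, y)
        Xtest = np.vstack([rng.normal(-3, 0.5, size=(10, 2)),
                           rng.normal(3, 0.5, size=(10, 2))])
        ytest = np.array([0] * 10 + [1] * 10)
        assert (model.predict(Xtest) == ytest).all()

    def test_rf_seeded_determinism(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, size=30)
        m1 = train_classifier("rf", X, y, seed=3)
        m2 = train_classifier("rf", X, y, seed=3)
        Xt = rng.normal(size=(10, 5))
        np.testing.assert_array_equal(m1.predict_proba(Xt), m2.predict_proba(Xt))

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(InvalidParameterError):
            train_classifier("knn", X, np.array([0, 1]))


class TestThreshold:
    def test_gap_returns_lowest_maximizer(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        # any threshold in (0.2, 0.8) is optimal; the scan returns the
        # lowest candidate, the midpoint 0.5
        assert select_threshold(scores, y) == pytest.approx(0.5)

    def test_oracle_scores(self):
        y = np.array([0, 1, 0, 1, 1])
        t = select_threshold(y.astype(float), y)
        assert 0 < t < 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = rng.uniform(size=30)
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            assert select_threshold(scores, y) == pytest.approx(
                oracles.threshold_scan_oracle(scores, y)
            )

    def test_constant_scores_default(self):
        assert select_threshold(np.full(10, 0.3), np.arange(10) % 2) == 0.5


class TestMetrics:
    def test_balanced_accuracy_hand_case(self):
        # 100 positives, 85 correct; 100 negatives, 87 correct
        y = np.array([1] * 100 + [0] * 100)
        pred = np.concatenate([np.ones(85), np.zeros(15), np.zeros(87), np.ones(13)])
        m = evaluate_split(pred, None, y)
        assert m["sensitivity"] == pytest.approx(0.85)
        assert m["specificity"] == pytest.approx(0.87)
        assert m["balanced_accuracy"] == pytest.approx(0.86)

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 1, 0])
        m = evaluate_split(y, y.astype(float), y)
        assert all(m[k] == pytest.approx(1.0) for k in m)

    def test_auc_equals_concordant_pair_count(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(size=40), 2)  # induce ties
            m = evaluate_split((scores > 0.5).astype(int), scores, y)
            assert m["auc"] == pytest.approx(
                oracles.auc_concordant_pairs(y, scores), abs=1e-12
            )

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 500 + [0] * 500)
        m = evaluate_split(np.zeros(1000), rng.uniform(size=1000), y)
        assert abs(m["auc"] - 0.5) < 0.1

    def test_single_class_test_set_flagged(self):
        y = np.ones(5, dtype=int)
        m = evaluate_split(np.ones(5), None, y)
        assert np.isnan(m["specificity"]) and np.isnan(m["auc"])
        assert m["sensitivity"] == 1.0


class TestPerPatientRate:
    def test_rate_arithmetic_and_inclusive_threshold(self):
        rows = []
        for r in range(100):
            rows.append({"classifier": "logreg", "repeat": r, "patient_id": "a",
                         "correct": r < 85})
            rows.append({"classifier": "logreg", "repeat": r, "patient_id": "b",
                         "correct": r < 80})
            rows.append({"classifier": "logreg", "repeat": r, "patient_id": "c",
                         "correct": r < 50})
        rates = per_patient_rate(pd.DataFrame(rows))
        assert rates.loc["a", "logreg"] == pytest.approx(0.85)
        assert rates.loc["b", "logreg"] == pytest.approx(0.80)
        # 0.80 counts ("at least 80%"); 0.50 does not
        assert bool(rates.loc["b", "all_classifiers"])
        assert not bool(rates.loc["c", "all_classifiers"])


class TestRunClassification:
    def test_report_shapes_and_ranges(self):
        table, y, _ = generate_feature_table(n_signal=3, n_noise=2, effect=2.5, seed=12)
        plan = make_split_plan(y, repeats=15, seed=2)
        report = run_classification(table, y, plan, seed=2)
        assert set(report.metrics.columns) == {"knn", "logreg", "rf"}
        vals = report.metrics.values
        assert ((vals >= 0) & (vals <= 1)).all()
        # balanced accuracy == (sens + spec)/2 per repeat
        pr = report.per_repeat.dropna(subset=["sensitivity", "specificity"])
        np.testing.assert_allclose(
            pr["balanced_accuracy"], (pr["sensitivity"] + pr["specificity"]) / 2
        )

    def test_seeded_repeatability(self):
        table, y, _ = generate_feature_table(n_signal=2, n_noise=2, seed=13)
        plan = make_split_plan(y, repeats=10, seed=3)
        r1 = run_classification(table, y, plan, seed=3)
        r2 = run_classification(table, y, plan, seed=3)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)
        pd.testing.assert_frame_equal(r1.patient_rates, r2.patient_rates)
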