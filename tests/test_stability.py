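"""ROI perturbation geometry, ICC(2,1) against ANOVA oracles, the
stability filter and the 2D-vs-3D reproducibility comparison."""

import numpy as np
import pandas as pd
import pytest

from ewing_radiomics.core import EmptyMaskError, PerturbationError, RoiMask
from ewing_radiomics.stability import (
    bounding_box,
    build_perturbation_set,
    compare_stability,
    icc_two_way_random,
    stability_filter,
    stable_fraction_summary,
    translate_roi,
)

import oracles


def _mask(voxels, shape=(20, 20, 10), spacing=(1, 1, 1), mode="3D"):
    m = np.zeros(shape, dtype=bool)
    for v in voxels:
        m[v] = True
    return RoiMask(m, spacing=spacing, mode=mode)


class TestBoundingBox:
    def test_point_mask(self):
        box = bounding_box(_mask([(3, 4, 5)]))
        assert box == [(3, 4), (4, 5), (5, 6)]
        assert [b - a for a, b in box] == [1, 1, 1]

    def test_full_grid(self):
        m = RoiMask(np.ones((6, 5, 4)), spacing=(1, 1, 1))
        assert bounding_box(m) == [(0, 6), (0, 5), (0, 4)]

    def test_matches_per_voxel_scan(self, small_cohort):
        _, cohort = small_cohort
        m = cohort[0].mask3d
        box = bounding_box(m)
        pts = np.argwhere(m.data)
        for ax in range(3):
            assert box[ax] == (pts[:, ax].min(), pts[:, ax].max() + 1)

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            bounding_box(RoiMask(np.zeros((4, 4, 4)), spacing=(1, 1, 1)))


class TestTranslateRoi:
    def test_ten_percent_of_box_length(self):
        m = np.zeros((60, 20, 5), dtype=bool)
        m[5:55, 8:12, 2] = True  # x-length 50 -> 5-voxel shift
        out = translate_roi(RoiMask(m, spacing=(1, 1, 1)), "x", +1)
        assert bounding_box(out)[0] == (10, 60)

    def test_minimum_one_voxel_floor(self):
        m = np.zeros((20, 20, 5), dtype=bool)
        m[8:12, 8:12, 2] = True  # length 4 -> round(0.4) = 0 -> floor 1
        out = translate_roi(RoiMask(m, spacing=(1, 1, 1)), "y", -1)
        assert bounding_box(out)[1] == (7, 11)

    def test_shift_then_reverse_restores(self):
        m = np.zeros((30, 30, 6), dtype=bool)
        m[10:20, 10:20, 2:4] = True
        r = RoiMask(m, spacing=(1, 1, 1))
        back = translate_roi(translate_roi(r, "x", +1), "x", -1)
        np.testing.assert_array_equal(back.data, r.data)

    def test_boundary_clipping_drops_voxels(self):
        m = np.zeros((10, 10, 4), dtype=bool)
        m[0:9, 2:5, 1] = True
        out = translate_roi(RoiMask(m, spacing=(1, 1, 1)), "x", -1)
        assert out.n_voxels < m.sum()

    def test_emptying_translation_raises(self):
        mask = _mask([(0, 5, 2)], shape=(2, 20, 5))  # x-length 1, shift 1 -> empty
        with pytest.raises(PerturbationError):
            translate_roi(mask, "x", -1)


class TestPerturbationSet:
    def test_five_masks_with_correct_shifts(self):
        rng = np.random.default_rng(31)
        for _ in range(3):
            # random box blob with ample margin so no boundary clipping
            m = np.zeros((60, 60, 20), dtype=bool)
            x0, y0, z0 = rng.integers(15, 20, size=3)
            lx, ly = rng.integers(5, 25, size=2)
            m[x0:x0 + lx, y0:y0 + ly, z0 % 10:z0 % 10 + 5] = True
            pert = build_perturbation_set(RoiMask(m, spacing=(1, 1, 1)))
            assert len(pert.masks) == 5
            box = bounding_box(pert.original)
            for axis, ax in (("x", 0), ("y", 1)):
                expect = max(1, round(0.10 * (box[ax][1] - box[ax][0])))
                for sign, key in ((+1, f"{axis}+"), (-1, f"{axis}-")):
                    shifted_box = bounding_box(pert.translated[key])
                    assert shifted_box[ax][0] - box[ax][0] == sign * expect
                    assert shifted_box[2] == box[2]  # z untouched

    def test_2d_masks_stay_single_slice(self):
        m = np.zeros((30, 30, 8), dtype=bool)
        m[10:20, 10:20, 3] = True
        pert = build_perturbation_set(RoiMask(m, spacing=(1, 1, 1), mode="2D"))
        for mask in pert.masks:
            assert mask.mode == "2D"
            assert np.unique(np.nonzero(mask.data)[2]).tolist() == [3]


class TestIcc:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        assert icc_two_way_random(x) == pytest.approx(1.0)

    def test_hand_matrix_matches_anova_oracle(self):
        x = np.array([
            [9.0, 2.0, 5.0],
            [6.0, 1.0, 3.0],
            [8.0, 4.0, 6.0],
            [7.0, 1.0, 2.0],
        ])
        # hand two-way ANOVA: grand = 4.5, SSR = 17, SSC = 62, SST = 83,
        # SSE = 4 -> MSR = 17/3, MSC = 31, MSE = 2/3
        # ICC = (17/3 - 2/3) / (17/3 + 2*(2/3) + (3/4)(31 - 2/3)) = 5/29.75
        assert icc_two_way_random(x) == pytest.approx(oracles.icc2_anova_oracle(x), abs=1e-12)
        assert icc_two_way_random(x) == pytest.approx(5.0 / 29.75, abs=1e-12)

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 6))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc_two_way_random(x) == pytest.approx(
                oracles.icc2_anova_oracle(x), abs=1e-10
            )

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x = rng.normal(size=(12, 4)) + 2 * rng.normal(size=(12, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "rater": np.tile(np.arange(4), 12),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        # ICC(A,1): absolute agreement, single rater == ICC(2,1)
        ref_val = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_way_random(x) == pytest.approx(ref_val, abs=1e-9)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 5))
        assert abs(icc_two_way_random(x)) < 0.1


def _tables_from_matrix(col_builder, n, features):
    """Build 5 aligned single-run tables; col_builder(feature, variant) -> n-vector."""
    idx = [f"p{i}" for i in range(n)]
    return [
        pd.DataFrame({f: col_builder(f, v) for f in features}, index=idx)
        for v in range(5)
    ]


class TestStabilityFilter:
    def test_translation_invariant_feature_is_stable(self):
        rng = np.random.default_rng(0)
        fixed = rng.normal(size=30)
        tables = _tables_from_matrix(
            lambda f, v: fixed.copy(), 30, ["const_across_variants"]
        )
        icc = stability_filter(tables)
        assert icc.loc["const_across_variants", "icc"] == pytest.approx(1.0)
        assert bool(icc.loc["const_across_variants", "stable"])

    def test_iid_noise_feature_unstable_at_n100(self):
        rng = np.random.default_rng(1)
        tables = _tables_from_matrix(
            lambda f, v: rng.normal(size=100), 100, ["noise"]
        )
        icc = stability_filter(tables)
        assert not bool(icc.loc["noise", "stable"])

    def test_threshold_is_strict(self):
        tables = _tables_from_matrix(lambda f, v: np.arange(10.0), 10, ["x"])
        icc = stability_filter(tables, threshold=1.0)
        # ICC exactly equals the threshold -> NOT stable (strict >)
        assert icc.loc["x", "icc"] == pytest.approx(1.0)
        assert not bool(icc.loc["x", "stable"])

    def test_noise_icc_decreases_with_noise_variance(self):
        """Adding noise of increasing variance to the translated copies
        drives ICC down (in expectation over replicates)."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        mean_icc = []
        for sd in (0.1, 0.5, 2.0):
            vals = []
            for _ in range(20):
                tables = [
                    pd.DataFrame({"f": base + (sd * rng.normal(size=40) if v else 0.0)},
                                 index=range(40))
                    for v in range(5)
                ]
                vals.append(stability_filter(tables)["icc"].iloc[0])
            mean_icc.append(np.mean(vals))
        assert mean_icc[0] > mean_icc[1] > mean_icc[2]

    def test_summary_fractions(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        tables = _tables_from_matrix(
            lambda f, v: base if f == "stable_one" else rng.normal(size=50),
            50, ["stable_one", "noisy_one"],
        )
        icc = stability_filter(tables)
        summary = stable_fraction_summary(icc)
        overall = summary[summary["group"] == "all"].iloc[0]
        assert overall["n_features"] == 2
        assert overall["n_stable"] == 1


class TestCompareStability:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, size=300)
        a = pd.DataFrame({"icc": vals})
        res = compare_stability(a, pd.DataFrame({"icc": vals.copy()}))
        assert abs(res["t"]) < 1e-9
        assert res["p"] > 0.99

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame({"icc": 0.9 + 0.02 * rng.normal(size=100)})
        b = pd.DataFrame({"icc": 0.5 + 0.02 * rng.normal(size=100)})
        assert compare_stability(a, b)["p"] < 1e-3

    def test_matches_welch_closed_form(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.8, 0.1, size=40)
        b = rng.normal(0.6, 0.2, size=55)
        res = compare_stability(pd.DataFrame({"icc": a}), pd.DataFrame({"icc": b}))
        t, dof, p = oracles.welch_oracle(a, b)
        assert res["t"] == pytest.approx(t, rel=1e-12)
        assert res["dof"] == pytest.approx(dof, rel=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-10)
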