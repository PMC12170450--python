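import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionmap.cohort import (
    ContingencyTable,
    chi_square_independence,
    classify_deficit,
    classify_roi_resection,
    contingency,
    dice,
    intersect_rois,
    odds_ratio,
    rank_sum,
    region_damage_percent,
    relative_risk,
)
from lesionmap.mask import LesionMask

AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


def mask_from_voxels(voxels, shape=(8, 8, 8)):
    data = np.zeros(shape, dtype=bool)
    for v in voxels:
        data[v] = True
    return LesionMask(data, AFFINE)


class TestDice:
    def test_identical_masks(self):
        m = mask_from_voxels([(1, 1, 1), (2, 2, 2)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = mask_from_voxels([(1, 1, 1)])
        b = mask_from_voxels([(5, 5, 5)])
        assert dice(a, b) == 0.0

    def test_forced_arithmetic(self):
        a = mask_from_voxels([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        b = mask_from_voxels([(0, 0, 0), (1, 0, 0)])
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_both_empty_warns_zero(self):
        e = mask_from_voxels([])
        with pytest.warns(UserWarning, match="empty"):
            assert dice(e, e) == 0.0

    def test_grid_mismatch(self):
        a = mask_from_voxels([(0, 0, 0)])
        b = LesionMask(a.data, np.eye(4))
        with pytest.raises(ValueError, match="different grids"):
            dice(a, b)


class TestIntersectRois:
    def test_subset_returns_subset(self):
        a = mask_from_voxels([(1, 1, 1)])
        b = mask_from_voxels([(1, 1, 1), (2, 2, 2)])
        np.testing.assert_array_equal(intersect_rois(a, b).data, a.data)

    def test_disjoint_warns_empty(self):
        a = mask_from_voxels([(1, 1, 1)])
        b = mask_from_voxels([(5, 5, 5)])
        with pytest.warns(UserWarning, match="empty"):
            assert intersect_rois(a, b).n_voxels == 0

    def test_random_pair_matches_voxel_loop(self):
        rng = np.random.default_rng(12)
        a = LesionMask(rng.random((6, 6, 6)) > 0.5, AFFINE)
        b = LesionMask(rng.random((6, 6, 6)) > 0.5, AFFINE)
        got = intersect_rois(a, b).data
        for idx in np.ndindex(6, 6, 6):
            assert got[idx] == (a.data[idx] and b.data[idx])


class TestClassification:
    def test_identical_dsc_flags_nobody(self):
        m = mask_from_voxels([(1, 1, 1)])
        with pytest.warns(UserWarning, match="zero standard deviation"):
            flags, dscs = classify_roi_resection([m, m, m], m)
        assert not flags.any()

    def test_single_outlier_flagged(self):
        roi = mask_from_voxels([(1, 1, 1), (1, 1, 2)])
        hit = mask_from_voxels([(1, 1, 1), (1, 1, 2)])
        miss = mask_from_voxels([(5, 5, 5)])
        flags, dscs = classify_roi_resection([miss] * 9 + [hit], roi)
        assert list(flags) == [False] * 9 + [True]

    def test_ten_dscs_match_longhand(self):
        roi = mask_from_voxels([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)])
        overlaps = [0, 0, 0, 1, 1, 2, 2, 3, 4, 4]
        masks = []
        for k in overlaps:
            vox = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)][:k]
            vox += [(5, 5, i) for i in range(4 - k)]  # keep each lesion 4 voxels
            masks.append(mask_from_voxels(vox))
        flags, dscs = classify_roi_resection(masks, roi)
        expected_dsc = np.array([2 * k / 8 for k in overlaps])
        np.testing.assert_allclose(dscs, expected_dsc)
        thr = expected_dsc.mean() + 1.5 * expected_dsc.std(ddof=1)
        np.testing.assert_array_equal(flags, expected_dsc >= thr)

    def test_deficit_aos_exclusion(self):
        df = pd.DataFrame(
            {
                "overall": [9.0] * 8,
                "self_generated": [9.0, 8.9, 9.0, 8.8, 8.9, 9.0, 2.0, 2.0],
                "aos_present": [False] * 7 + [True],
            }
        )
        flags, d = classify_deficit(df)
        assert flags[6]  # large discrepancy, no AOS
        assert not flags[7]  # same discrepancy but AOS present
        np.testing.assert_allclose(d, df["overall"] - df["self_generated"])

    def test_equal_differences_flag_nobody(self):
        df = pd.DataFrame(
            {
                "overall": [5.0, 6.0, 7.0],
                "self_generated": [4.0, 5.0, 6.0],
                "aos_present": [False] * 3,
            }
        )
        with pytest.warns(UserWarning, match="zero standard deviation"):
            flags, _ = classify_deficit(df)
        assert not flags.any()

    def test_eight_subject_longhand(self):
        rng = np.random.default_rng(13)
        overall = rng.uniform(5, 10, 8).round(2)
        selfg = rng.uniform(0, 10, 8).round(2)
        df = pd.DataFrame(
            {"overall": overall, "self_generated": selfg, "aos_present": [False] * 8}
        )
        flags, d = classify_deficit(df)
        dd = overall - selfg
        thr = dd.mean() + 1.5 * dd.std(ddof=1)
        np.testing.assert_array_equal(flags, dd >= thr)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(14)
        overall = rng.uniform(5, 10, 12)
        selfg = rng.uniform(0, 10, 12)
        aos = rng.random(12) > 0.8
        df = pd.DataFrame(
            {"overall": overall, "self_generated": selfg, "aos_present": aos}
        )
        flags, _ = classify_deficit(df)
        order = rng.permutation(12)
        flags2, _ = classify_deficit(df.iloc[order].reset_index(drop=True))
        np.testing.assert_array_equal(flags[order], flags2)


class TestContingency:
    def test_one_each(self):
        t = contingency([True, True, False, False], [True, False, True, False])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_reconstructed_cohort_counts(self):
        # N=307; 18 ROI resections, 19 deficits, 9 joint
        roi = np.zeros(307, dtype=bool)
        deficit = np.zeros(307, dtype=bool)
        roi[:18] = True
        deficit[:9] = True  # joint
        deficit[18:28] = True  # deficit without ROI resection
        t = contingency(roi, deficit)
        assert (t.a, t.b, t.c, t.d) == (9, 9, 10, 279)

    def test_all_false(self):
        t = contingency([False] * 7, [False] * 7)
        assert t.d == 7 and t.n == 7

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ContingencyTable(-1, 0, 0, 0)


class TestEffectEstimates:
    TABLE = ContingencyTable(9, 9, 10, 279)

    def test_rr_matches_published_values(self):
        rr = relative_risk(self.TABLE)
        assert round(rr.point, 2) == 14.45
        assert round(rr.ci_low, 2) == 6.73
        assert round(rr.ci_high, 2) == 31.03

    def test_or_matches_published_values(self):
        orr = odds_ratio(self.TABLE)
        assert round(orr.point, 2) == 27.90
        assert round(orr.ci_low, 2) == 9.11
        assert round(orr.ci_high, 2) == 85.40

    def test_equal_risks_give_unity(self):
        assert relative_risk(ContingencyTable(5, 5, 5, 5)).point == pytest.approx(1.0)
        rr = relative_risk(ContingencyTable(5, 5, 5, 5))
        assert rr.ci_low < 1.0 < rr.ci_high

    def test_or_unity_by_arithmetic(self):
        assert odds_ratio(ContingencyTable(2, 4, 3, 6)).point == pytest.approx(1.0)

    def test_row_swap_inverts_rr(self):
        t = ContingencyTable(9, 9, 10, 279)
        swapped = ContingencyTable(10, 279, 9, 9)
        assert relative_risk(t).point == pytest.approx(1 / relative_risk(swapped).point)

    def test_or_exceeds_rr_and_cis_exclude_one(self):
        rr = relative_risk(self.TABLE)
        orr = odds_ratio(self.TABLE)
        assert orr.point > rr.point > 1.0
        assert rr.ci_low > 1.0 and orr.ci_low > 1.0

    def test_zero_cells_error_and_continuity_flag(self):
        t = ContingencyTable(0, 10, 5, 5)
        with pytest.raises(ValueError, match="continuity"):
            relative_risk(t)
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio(t)
        assert relative_risk(t, continuity_correction=True).point > 0
        assert odds_ratio(t, continuity_correction=True).point > 0


class TestChiSquare:
    def test_identical_proportions_zero(self):
        a = ["x"] * 10 + ["y"] * 10
        b = ["p", "q"] * 10
        chi2, dof, p = chi_square_independence(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_2x2_balanced_zero(self):
        a = ["u"] * 20 + ["v"] * 20
        b = (["l"] * 10 + ["r"] * 10) * 2
        chi2, dof, _ = chi_square_independence(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 1

    def test_4x2_matches_longhand(self):
        rng = np.random.default_rng(15)
        a = rng.choice(["e1", "e2", "e3", "e4"], 40)
        b = rng.choice(["yes", "no"], 40)
        # ensure all levels appear
        a[:4] = ["e1", "e2", "e3", "e4"]
        b[:2] = ["yes", "no"]
        chi2, dof, p = chi_square_independence(a, b)
        obs = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(float)
        expected = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / obs.sum()
        longhand = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(longhand, abs=1e-12)
        assert dof == 3
        assert p == pytest.approx(stats.chi2.sf(longhand, 3))

    def test_unused_category_dropped_with_warning(self):
        a = pd.Categorical(["x"] * 6 + ["y"] * 6, categories=["x", "y", "z"])
        b = ["p", "q"] * 6
        with pytest.warns(UserWarning, match="zero-marginal"):
            chi2, dof, _ = chi_square_independence(a, b)
        assert dof == 1

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            chi_square_independence(["x"] * 4, ["p", "q", "p", "q"])


class TestRankSum:
    def test_complete_separation_max_u(self):
        u, _ = rank_sum([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert u == 9.0

    def test_identical_multisets_half_u(self):
        u, p = rank_sum([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert u == pytest.approx(4.5)

    def test_matches_scipy_u(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(size=8), rng.normal(size=11)
        u, _ = rank_sum(a, b)
        assert u == stats.mannwhitneyu(a, b).statistic

    def test_enumeration_oracle_4_vs_5(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        u, p = rank_sum(a, b)

        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        mu = 4 * 5 / 2.0
        obs = abs(ranks[:4].sum() - 4 * 5 / 2.0 - mu)
        count = total = 0
        for idx in itertools.combinations(range(9), 4):
            u_perm = ranks[list(idx)].sum() - 4 * 5 / 2.0
            count += abs(u_perm - mu) >= obs - 1e-12
            total += 1
        assert total == 126
        assert p == pytest.approx(count / total, abs=1e-12)
        assert u == pytest.approx(ranks[:4].sum() - 4 * 5 / 2.0)

    def test_ties_handled_with_midranks(self):
        u, p = rank_sum([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
        assert 0 < p <= 1.0

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(18)
        a = rng.normal(0.8, 1, 60)
        b = rng.normal(0, 1, 60)
        u, p = rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_sum([], [1.0])


class TestRegionDamage:
    def _atlas(self):
        atlas = np.zeros((8, 8, 8), dtype=int)
        atlas[0:2, 0:2, 0:2] = 7  # 8-voxel region
        return atlas

    def test_full_coverage(self):
        mask = mask_from_voxels([(i, j, k) for i in range(2) for j in range(2) for k in range(2)])
        assert region_damage_percent(mask, self._atlas(), 7) == 100.0

    def test_disjoint_zero(self):
        mask = mask_from_voxels([(5, 5, 5)])
        assert region_damage_percent(mask, self._atlas(), 7) == 0.0

    def test_half_of_eight_voxel_region(self):
        mask = mask_from_voxels([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)])
        assert region_damage_percent(mask, self._atlas(), 7) == 50.0

    def test_absent_label_errors(self):
        with pytest.raises(ValueError, match="label 99"):
            region_damage_percent(mask_from_voxels([(0, 0, 0)]), self._atlas(), 99)
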