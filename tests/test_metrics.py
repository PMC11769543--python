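"""Voxel metrics against brute-force oracles; detection protocol behaviour."""

import numpy as np
import pytest
from scipy import ndimage

from renalseg import metrics as M


def brute_confusion(pred, gt):
    """Exhaustive per-voxel enumeration oracle."""
    tp = fp = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g and not p:
            fn += 1
    return tp, fp, fn


class TestVoxelMetrics:
    def test_confusion_matches_enumeration_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            shape = tuple(rng.integers(1, 9, size=3))
            pred = rng.random(shape) > rng.random()
            gt = rng.random(shape) > rng.random()
            c = M.voxel_confusion(pred, gt)
            tp, fp, fn = brute_confusion(pred, gt)
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn)

    def test_formulas_on_direct_substitution(self):
        c = M.VoxelConfusion(tp=3, fp=1, fn=1)
        assert M.dice(c) == pytest.approx(0.75)
        assert M.precision(c) == pytest.approx(0.75)
        assert M.vd(c) == pytest.approx(0.0)
        assert M.osr(c) == pytest.approx(0.25)
        assert M.usr(c) == pytest.approx(0.25)

    def test_perfect_prediction(self):
        c = M.VoxelConfusion(tp=10, fp=0, fn=0)
        assert M.dice(c) == 1.0
        assert M.vd(c) == 0.0
        assert M.osr(c) == 0.0
        assert M.usr(c) == 0.0

    def test_empty_prediction(self):
        gt = np.zeros((4, 4, 4), bool)
        gt[1:3, 1:3, 1] = True
        c = M.voxel_confusion(np.zeros_like(gt), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, 4)
        assert M.dice(c) == 0.0
        assert M.usr(c) == 1.0
        assert M.osr(c) == 0.0

    def test_degenerate_empty_both(self):
        c = M.VoxelConfusion(tp=0, fp=0, fn=0)
        assert M.dice(c) == 1.0
        assert M.vd(c) == M.osr(c) == M.usr(c) == 0.0

    def test_osr_plus_usr_identity_on_random_confusions(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(0, 100, size=3))
            if tp + fn == 0:
                continue
            c = M.VoxelConfusion(tp=tp, fp=fp, fn=fn)
            assert M.osr(c) + M.usr(c) == pytest.approx((fp + fn) / (tp + fn))

    def test_dice_one_iff_no_errors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(0, 10, size=3))
            if tp + fp + fn == 0:
                continue
            c = M.VoxelConfusion(tp=tp, fp=fp, fn=fn)
            is_perfect = fp == 0 and fn == 0
            assert (M.dice(c) == 1.0) == is_perfect
            if is_perfect:
                assert M.vd(c) == M.osr(c) == M.usr(c) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.voxel_confusion(np.zeros((3, 3, 3)), np.zeros((3, 3, 4)))


class TestDiameterAndCategories:
    def test_single_voxel_measures_one_voxel_extent(self):
        d = M.tumor_diameter(np.array([[5, 5, 5]]), (1.0, 1.0, 1.0))
        assert d == pytest.approx(0.1)

    def test_axial_disk_radius_15(self):
        grid = np.zeros((40, 40, 5), bool)
        xx, yy = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        grid[..., 2] = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15 ** 2
        d = M.tumor_diameter(np.argwhere(grid), (1.0, 1.0, 1.0))
        assert d == pytest.approx(3.0, abs=0.1)

    def test_tall_thin_cylinder_measures_inplane_extent(self):
        # craniocaudal cylinder: 60 voxels tall, radius 5 in plane
        grid = np.zeros((16, 16, 60), bool)
        xx, yy = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        disk = (xx - 8) ** 2 + (yy - 8) ** 2 <= 5 ** 2
        grid[disk, :] = True
        d = M.tumor_diameter(np.argwhere(grid), (1.0, 1.0, 1.0))
        assert d == pytest.approx(1.0, abs=0.15)  # in-plane ~10 mm, not 60
        d3 = M.tumor_diameter_feret3d(np.argwhere(grid), (1.0, 1.0, 1.0))
        assert d3 > 5.0  # the 3-D Feret measure does see the height

    @pytest.mark.parametrize("d_cm,category", [
        (1.0, "small"), (4.0, "small"), (4.05, "medium"),
        (7.0, "medium"), (7.05, "large"),
    ])
    def test_size_category_boundaries(self, d_cm, category):
        assert M.size_category(d_cm) == category

    @pytest.mark.parametrize("d_cm,sub", [
        (1.5, "<=2cm"), (2.0, "<=2cm"), (2.5, ">2-<=3cm"),
        (3.0, ">2-<=3cm"), (3.5, ">3-<=4cm"), (4.5, None),
    ])
    def test_small_subcategories(self, d_cm, sub):
        assert M.small_subcategory(d_cm) == sub

    def test_sphere_instance_measured_and_binned(self):
        grid = np.zeros((40, 40, 40), bool)
        g = np.meshgrid(*[np.arange(40)] * 3, indexing="ij")
        grid[sum((a - 20.0) ** 2 for a in g) <= 10 ** 2] = True
        inst = M.instance_components(grid, (1.0, 1.0, 1.0))
        assert len(inst) == 1
        assert inst[0].diameter_cm == pytest.approx(2.0, abs=0.1)
        assert inst[0].category == "small"
        assert inst[0].subcategory == "<=2cm"

    def test_empty_mask_yields_no_instances(self):
        assert M.instance_components(np.zeros((5, 5, 5), bool), (1, 1, 1)) == []

    def test_small_components_discarded_as_noise(self):
        grid = np.zeros((10, 10, 10), bool)
        grid[1, 1, 1] = True  # 1 voxel, below default minimum
        grid[5:8, 5:8, 5:8] = True  # 27 voxels
        inst = M.instance_components(grid, (1, 1, 1))
        assert len(inst) == 1
        assert inst[0].n_voxels == 27


class TestDetection:
    def _cube_instances(self):
        gt = np.zeros((12, 12, 12), bool)
        pred = np.zeros((12, 12, 12), bool)
        gt[2:6, 2:6, 2:6] = True  # 4x4x4 cube
        pred[4:8, 2:6, 2:6] = True  # shifted: overlap 2x4x4 = 32, union 96
        gi = M.instance_components(gt, (1, 1, 1), min_component_voxels=1)
        pi = M.instance_components(pred, (1, 1, 1), min_component_voxels=1)
        return gi, pi

    def test_two_cube_overlap_detected_at_quarter_iou(self):
        gi, pi = self._cube_instances()
        res = M.match_detections(gi, pi, iou_threshold=0.25)
        assert len(res.matches) == 1
        assert res.matches[0][2] == pytest.approx(32 / 96)
        assert res.detected_gt_ids == [gi[0].component_id]
        assert res.unmatched_pred_ids == []

    def test_two_cube_overlap_missed_at_higher_threshold(self):
        gi, pi = self._cube_instances()
        res = M.match_detections(gi, pi, iou_threshold=0.35)
        assert res.matches == []
        assert res.unmatched_pred_ids == [pi[0].component_id]

    def test_identical_instances_have_unit_iou(self):
        gt = np.zeros((8, 8, 8), bool)
        gt[2:5, 2:5, 2:5] = True
        gi = M.instance_components(gt, (1, 1, 1), min_component_voxels=1)
        res = M.match_detections(gi, gi)
        assert res.matches[0][2] == 1.0

    def test_disjoint_instances_are_miss_and_false_positive(self):
        gt = np.zeros((10, 10, 10), bool)
        pred = np.zeros((10, 10, 10), bool)
        gt[0:3, 0:3, 0:3] = True
        pred[6:9, 6:9, 6:9] = True
        gi = M.instance_components(gt, (1, 1, 1), min_component_voxels=1)
        pi = M.instance_components(pred, (1, 1, 1), min_component_voxels=1)
        res = M.match_detections(gi, pi)
        assert res.detected_gt_ids == []
        assert len(res.unmatched_pred_ids) == 1

    def test_detection_monotone_in_threshold(self, rng):
        # random blobs: lowering the threshold never loses detections
        for _ in range(10):
            gt = rng.random((10, 10, 10)) > 0.7
            pred = rng.random((10, 10, 10)) > 0.7
            gi = M.instance_components(gt, (1, 1, 1), min_component_voxels=1)
            pi = M.instance_components(pred, (1, 1, 1), min_component_voxels=1)
            n_prev = None
            for thr in (0.6, 0.4, 0.25, 0.1):
                n = len(M.match_detections(gi, pi, thr).detected_gt_ids)
                if n_prev is not None:
                    assert n >= n_prev
                n_prev = n

    def test_matching_is_one_to_one(self, rng):
        gt = rng.random((12, 12, 12)) > 0.6
        pred = rng.random((12, 12, 12)) > 0.6
        gi = M.instance_components(gt, (1, 1, 1), min_component_voxels=1)
        pi = M.instance_components(pred, (1, 1, 1), min_component_voxels=1)
        res = M.match_detections(gi, pi, 0.1)
        gts = [m[0] for m in res.matches]
        prs = [m[1] for m in res.matches]
        assert len(gts) == len(set(gts)) and len(prs) == len(set(prs))


class TestSummarize:
    def _case(self, case_id, gt, pred):
        return M.evaluate_case(case_id, gt, pred, (1.0, 1.0, 1.0),
                               min_component_voxels=1)

    def test_half_detected_small_tumors(self):
        gt = np.zeros((30, 30, 10), bool)
        gt[2:8, 2:8, 2:8] = True
        gt[20:26, 20:26, 2:8] = True
        pred = np.zeros_like(gt)
        pred[2:8, 2:8, 2:8] = True  # only the first detected
        df = M.summarize([self._case("a", gt, pred)]).set_index("category")
        assert df.loc["small", "n_gt"] == 2
        assert df.loc["small", "sensitivity"] == pytest.approx(0.5)

    def test_fpc_averages_over_patients(self):
        gt = np.zeros((20, 20, 10), bool)
        fp1 = np.zeros_like(gt)
        fp1[1:5, 1:5, 1:5] = True
        fp1[10:14, 10:14, 1:5] = True
        fp2 = np.zeros_like(gt)
        fp2[1:5, 1:5, 1:5] = True
        cases = [self._case("a", gt, fp1), self._case("b", gt, fp2)]
        df = M.summarize(cases).set_index("category")
        assert df.loc["small", "n_fp"] == 3
        assert df.loc["small", "fpc"] == pytest.approx(1.5)

    def test_planted_cohort_matches_hand_table(self):
        # 3 patients: 2 small GT (1 detected), 1 medium GT (detected), 1 FP
        cases = []
        g1 = np.zeros((60, 60, 20), bool)
        g1[5:15, 5:15, 5:15] = True  # ~1.3 cm small
        p1 = np.zeros_like(g1)
        p1[5:15, 5:15, 5:15] = True
        cases.append(self._case("c1", g1, p1))
        g2 = np.zeros((80, 80, 30), bool)
        g2[10:55, 10:55, 5:25] = True  # 45 mm in-plane: medium
        p2 = np.zeros_like(g2)
        p2[10:55, 10:55, 5:25] = True
        cases.append(self._case("c2", g2, p2))
        g3 = np.zeros((60, 60, 20), bool)
        g3[5:15, 5:15, 5:15] = True  # small, missed
        p3 = np.zeros_like(g3)
        p3[30:40, 30:40, 5:15] = True  # disjoint FP (small-sized)
        cases.append(self._case("c3", g3, p3))
        df = M.summarize(cases).set_index("category")
        assert df.loc["small", "n_gt"] == 2
        assert df.loc["small", "n_detected"] == 1
        assert df.loc["small", "sensitivity"] == pytest.approx(0.5)
        assert df.loc["small", "n_fp"] == 1
        assert df.loc["small", "fpc"] == pytest.approx(1 / 3)
        assert df.loc["medium", "sensitivity"] == pytest.approx(1.0)
        assert df.loc["medium", "dice_mean"] == pytest.approx(1.0)
        assert np.isnan(df.loc["large", "sensitivity"])  # no large GT


class TestCompareDice:
    def test_identical_lists_give_p_one(self):
        a = [0.8, 0.7, 0.9, 0.85, 0.75, 0.8]
        assert M.compare_dice(a, a) == 1.0

    def test_systematic_shift_is_significant(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.5, 0.7, size=20)
        b = a + 0.2
        assert M.compare_dice(a, b) < 0.01

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.4, 0.9, size=12)
        b = a + rng.normal(0, 0.05, size=12)
        perm = rng.permutation(12)
        assert M.compare_dice(a, b) == pytest.approx(M.compare_dice(a[perm], b[perm]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            M.compare_dice([0.5] * 6, [0.5] * 7)
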