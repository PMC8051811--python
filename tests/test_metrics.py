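"""IoU matrix, matching, and precision/recall/F1 identities."""

import numpy as np
import pytest

from nucannotate.metrics import (
    ConfusionCounts,
    annotation_accuracy,
    evaluate_pair,
    f1_curve,
    iou_matrix,
    match_at_threshold,
    prf1,
)


from tests_support import brute_force_max_matching, random_label_maps


class TestIoUMatrix:
    def test_identity_pairs_have_iou_one(self, small_field):
        _, gt = small_field
        mat = iou_matrix(gt.label_map, gt.label_map)
        assert mat.n_gt == mat.n_pred == len(gt.objects)
        diag = mat.pairs[mat.pairs["gt_id"] == mat.pairs["pred_id"]]
        assert len(diag) == mat.n_gt
        assert (diag["iou"] == 1.0).all()

    def test_hand_counted_partial_overlap(self):
        # gt instance of 4 px and pred of 4 px overlapping in 2 px: IoU = 2/6
        gt = np.zeros((4, 4), np.int32)
        pred = np.zeros((4, 4), np.int32)
        gt[0, 0:4] = 1
        pred[0, 2:4] = 1
        pred[1, 2:4] = 1
        mat = iou_matrix(gt, pred)
        assert len(mat.pairs) == 1
        row = mat.pairs.iloc[0]
        assert row["intersection_px"] == 2 and row["union_px"] == 6
        assert row["iou"] == pytest.approx(2 / 6)

    def test_disjoint_maps_have_no_pairs(self):
        gt = np.zeros((8, 8), np.int32)
        pred = np.zeros((8, 8), np.int32)
        gt[0, 0], pred[7, 7] = 1, 1
        assert iou_matrix(gt, pred).pairs.empty

    def test_symmetry_under_transposition(self, small_field):
        _, gt = small_field
        noisy = np.roll(gt.label_map, 2, axis=0)
        a = iou_matrix(gt.label_map, noisy).pairs
        b = iou_matrix(noisy, gt.label_map).pairs
        a_set = {(r.gt_id, r.pred_id, r.iou) for r in a.itertuples(index=False)}
        b_set = {(r.pred_id, r.gt_id, r.iou) for r in b.itertuples(index=False)}
        assert a_set == b_set

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou_matrix(np.zeros((4, 4), np.int32), np.zeros((5, 5), np.int32))


class TestMatching:
    def test_identity_gives_all_tp(self, small_field):
        _, gt = small_field
        counts = match_at_threshold(iou_matrix(gt.label_map, gt.label_map), 0.5)
        assert counts.tp == len(gt.objects) and counts.fp == counts.fn == 0

    def test_below_threshold_pair_is_fp_plus_fn(self):
        gt = np.zeros((4, 4), np.int32)
        pred = np.zeros((4, 4), np.int32)
        gt[0, 0:4] = 1
        pred[0:2, 2:4] = 1  # IoU 2/6 < 0.5
        counts = match_at_threshold(iou_matrix(gt, pred), 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_count_conservation_and_greedy_optimality(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            gt, pred = random_label_maps(rng)
            mat = iou_matrix(gt, pred)
            counts = match_at_threshold(mat, 0.5)
            assert counts.tp + counts.fn == mat.n_gt
            assert counts.tp + counts.fp == mat.n_pred
            assert counts.tp == brute_force_max_matching(mat, 0.5)

    def test_permutation_invariance(self, small_field):
        _, gt = small_field
        pred = np.roll(gt.label_map, 1, axis=1)
        perm = np.zeros(gt.label_map.max() + 1, np.int32)
        labels = np.arange(1, gt.label_map.max() + 1)
        perm[labels] = np.roll(labels, 3)
        m1 = evaluate_pair(gt.label_map, pred, 0.5)
        m2 = evaluate_pair(perm[gt.label_map], pred, 0.5)
        assert (m1.precision, m1.recall, m1.f1) == (m2.precision, m2.recall, m2.f1)


class TestPRF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r,f1",
        [
            (3, 1, 2, 0.75, 0.6, 3 / 4.5),
            (0, 0, 0, 0.0, 0.0, 0.0),
            (5, 0, 0, 1.0, 1.0, 1.0),
            (0, 3, 4, 0.0, 0.0, 0.0),
        ],
    )
    def test_formulas_on_enumerated_counts(self, tp, fp, fn, p, r, f1):
        m = prf1(ConfusionCounts(t=0.5, tp=tp, fp=fp, fn=fn, matches=[(i, i, 1.0) for i in range(tp)]))
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f1 == pytest.approx(f1)

    def test_f1_is_harmonic_mean_when_defined(self):
        m = prf1(ConfusionCounts(t=0.5, tp=3, fp=1, fn=2))
        assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))


class TestF1Curve:
    def test_identity_is_one_everywhere(self, small_field):
        _, gt = small_field
        curve = f1_curve(gt.label_map, gt.label_map)
        assert len(curve) == 6
        assert (curve["f1"] == 1.0).all()

    def test_f1_non_increasing_in_threshold(self):
        rng = np.random.default_rng(23)
        grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
        for _ in range(10):
            gt, pred = random_label_maps(rng)
            curve = f1_curve(gt, pred, thresholds=grid)
            assert (np.diff(curve["f1"]) <= 1e-12).all()

    def test_eroded_prediction_passes_low_thresholds_only(self):
        from scipy import ndimage as ndi

        gt = np.zeros((60, 60), np.int32)
        rr, cc = np.ogrid[:60, :60]
        for k, (r, c) in enumerate([(15, 15), (15, 45), (45, 30)], start=1):
            gt[(rr - r) ** 2 + (cc - c) ** 2 <= 100] = k
        pred = np.where(ndi.binary_erosion(gt > 0, iterations=1), gt, 0)
        curve = f1_curve(gt, pred).set_index("iou_threshold")
        assert curve.loc[0.50, "f1"] == 1.0
        assert curve.loc[0.95, "f1"] == 0.0


class TestAnnotationAccuracy:
    def test_perfect_auto_mask_either_mode(self, small_field):
        _, gt = small_field
        for restrict in (False, True):
            m = annotation_accuracy(gt.label_map, gt.label_map, restrict_to_kept=restrict)
            assert m.mean_iou_all == m.mean_iou_matched == 1.0

    def test_empty_auto_mask_unrestricted(self, small_field):
        _, gt = small_field
        m = annotation_accuracy(gt.label_map, np.zeros_like(gt.label_map))
        assert m.mean_iou_all == 0.0 and m.f1 == 0.0

    def test_restricting_to_kept_raises_mean_iou(self, singles_field):
        # dropping 3 of 10 detected objects via the kept set: the
        # restricted matched mean must exceed the unrestricted all-gt mean
        _, _, gt = singles_field
        auto = gt.label_map
        kept = set(range(1, 8))  # exclude labels 8..10
        unrestricted = annotation_accuracy(gt.label_map, auto, kept=kept)
        restricted = annotation_accuracy(gt.label_map, auto, kept=kept, restrict_to_kept=True)
        assert unrestricted.mean_iou_all < restricted.mean_iou_matched
        assert restricted.f1 == 1.0 and unrestricted.f1 < 1.0
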