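import numpy as np
import pytest

from oralseg.label_scheme import default_scheme
from oralseg.metrics import (EvaluationPolicy, class_metrics, confusion_counts,
                             evaluate_case, macro_average, tally_identification)
from oralseg.phantom import perturb_annotation
from oralseg.volume_io import LabelVolume

from conftest import random_label_pair


def brute_force_counts(pred, gt, k):
    """Independent per-voxel enumeration oracle."""
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p == k and g == k:
            tp += 1
        elif p == k:
            fp += 1
        elif g == k:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def make_lv(labels):
    return LabelVolume(labels=np.asarray(labels, dtype=np.int16),
                       spacing=(1, 1, 1))


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self, rng):
        _, gt = random_label_pair(rng)
        tp, fp, fn, tn = confusion_counts(gt, gt, 2)
        assert fp == 0 and fn == 0
        assert tp + tn == gt.labels.size

    def test_matches_per_voxel_enumeration(self, rng):
        for _ in range(20):
            pred, gt = random_label_pair(rng)
            for k in range(0, 5):
                assert confusion_counts(pred, gt, k) == \
                    brute_force_counts(pred.labels, gt.labels, k)

    def test_complement_swap_symmetry(self, rng):
        pred, gt = random_label_pair(rng, n_classes=1)
        tp, fp, fn, tn = confusion_counts(pred, gt, 1)
        # swapping which class counts as "positive" swaps TP<->TN, FP<->FN
        tp0, fp0, fn0, tn0 = confusion_counts(pred, gt, 0)
        assert (tp0, fp0, fn0, tn0) == (tn, fn, fp, tp)

    def test_grid_mismatch_is_contract_error(self):
        with pytest.raises(ValueError, match="grids"):
            confusion_counts(make_lv(np.zeros((3, 3, 3))),
                             make_lv(np.zeros((4, 4, 4))), 1)


class TestClassMetrics:
    def test_textbook_counts(self):
        m = class_metrics(tp=3, fp=3, fn=1, tn=3)
        assert m.dice == pytest.approx(0.6)
        assert m.iou == pytest.approx(3 / 7)
        assert m.precision == pytest.approx(0.5)
        assert m.sensitivity == pytest.approx(0.75)

    def test_perfect_prediction_scores_one_everywhere(self):
        m = class_metrics(tp=10, fp=0, fn=0, tn=90)
        assert (m.dice, m.iou, m.accuracy, m.precision, m.sensitivity,
                m.f1) == (1, 1, 1, 1, 1, 1)

    def test_no_overlap_scores_zero(self):
        m = class_metrics(tp=0, fp=4, fn=6, tn=90)
        assert m.dice == 0.0 and m.iou == 0.0

    def test_f1_equals_dice_on_random_counts(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            m = class_metrics(int(tp), int(fp), int(fn), int(tn))
            assert m.f1 == m.dice

    def test_iou_never_exceeds_dice(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 30, size=4))
            m = class_metrics(tp, fp, fn, tn)
            assert m.iou <= m.dice + 1e-12
            if m.iou not in (0.0, 1.0):
                assert m.iou < m.dice

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(-1, 0, 0, 0)


class TestMacroAverage:
    def test_arithmetic_mean(self):
        mean, n = macro_average({1: 0.8, 2: 0.9, 3: 1.0})
        assert mean == pytest.approx(0.9) and n == 3

    def test_single_class(self):
        assert macro_average({7: 0.42}) == (pytest.approx(0.42), 1)

    def test_all_equal_values_are_a_fixed_point(self):
        mean, _ = macro_average({k: 0.77 for k in range(5)})
        assert mean == pytest.approx(0.77)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            macro_average({}, set())


class TestIdentificationTally:
    def test_empty_class_predicted_empty_is_correct_identify(self, scheme):
        gt = np.zeros((6, 6, 6), dtype=np.int16)
        gt[0, 0, 0] = 1
        pred = gt.copy()
        tally = tally_identification(make_lv(pred), make_lv(gt), scheme)
        assert 18 in tally.gt_empty_classes
        assert tally.correct_identify == 35
        assert tally.false_identify == 0
        assert tally.missing_segment == 0

    def test_bridge_style_false_identification(self, scheme):
        """A structure predicted where the ground truth is empty (e.g. a
        bridge segmented as a tooth) counts as a false identification."""
        gt = np.zeros((8, 8, 8), dtype=np.int16)
        gt[0:2, 0:2, 0:2] = scheme.fdi_to_index(16)
        pred = gt.copy()
        pred[4:6, 4:6, 4:6] = scheme.fdi_to_index(15)  # gt-empty class
        tally = tally_identification(make_lv(pred), make_lv(gt), scheme)
        assert scheme.fdi_to_index(15) in tally.false_identify_classes
        assert tally.false_identify == 1

    def test_constructed_hand_tally(self, scheme):
        """gt present {1,2,33,34}, gt empty rest; pred present {1,3,33,34}:
        class 3 is falsely identified, class 2 is a missing segment."""
        gt = np.zeros((8, 8, 8), dtype=np.int16)
        pred = np.zeros((8, 8, 8), dtype=np.int16)
        for i, k in enumerate([1, 2, 33, 34]):
            gt[i, :2, :2] = k
        for i, k in enumerate([1, 3, 33, 34]):
            pred[i, :2, :2] = k
        tally = tally_identification(make_lv(pred), make_lv(gt), scheme)
        assert tally.false_identify == 1
        assert tally.missing_segment == 1
        assert tally.missing_segment_classes == (2,)
        assert tally.correct_identify == len(tally.gt_empty_classes) - 1

    def test_correct_plus_false_equals_gt_empty_count(self, rng, scheme):
        for _ in range(10):
            pred, gt = random_label_pair(rng, shape=(6, 6, 6), n_classes=36)
            tally = tally_identification(pred, gt, scheme)
            assert tally.correct_identify + tally.false_identify == \
                len(tally.gt_empty_classes)

    def test_min_voxels_threshold(self, scheme):
        gt = np.zeros((6, 6, 6), dtype=np.int16)
        pred = np.zeros((6, 6, 6), dtype=np.int16)
        pred[0, 0, 0] = 5  # a single-voxel blob
        t1 = tally_identification(make_lv(pred), make_lv(gt), scheme,
                                  min_voxels=1)
        t2 = tally_identification(make_lv(pred), make_lv(gt), scheme,
                                  min_voxels=2)
        assert t1.false_identify == 1 and t2.false_identify == 0


class TestEvaluateCase:
    def test_perfect_prediction_scores_unity(self, small_phantom, scheme):
        _, lv = small_phantom
        report, tally = evaluate_case(lv, lv, scheme)
        assert report.macro["mDice"] == 1.0
        assert report.macro["mIoU"] == 1.0
        assert tally.false_identify == 0 and tally.missing_segment == 0

    def test_perturbed_annotation_scores_strictly_between_zero_and_one(
            self, small_phantom, scheme):
        _, lv = small_phantom
        pert = perturb_annotation(lv, 0.25, seed=9)
        report, _ = evaluate_case(pert, lv, scheme)
        assert 0.0 < report.macro["mDice"] < 1.0
        # reproducible for a fixed seed
        report2, _ = evaluate_case(perturb_annotation(lv, 0.25, seed=9), lv,
                                   scheme)
        assert report2.macro["mDice"] == report.macro["mDice"]

    def test_background_inclusion_inflates_accuracy(self, scheme):
        gt = np.zeros((10, 10, 10), dtype=np.int16)
        gt[0:2, 0:2, 0:2] = 1
        pred = np.zeros_like(gt)
        pred[0:2, 0:2, 0:1] = 1
        rep_ex, _ = evaluate_case(make_lv(pred), make_lv(gt), scheme,
                                  EvaluationPolicy(include_background=False))
        rep_in, _ = evaluate_case(make_lv(pred), make_lv(gt), scheme,
                                  EvaluationPolicy(include_background=True))
        assert rep_in.macro["mDice"] >= rep_ex.macro["mDice"]
        assert rep_in.n_classes_averaged == rep_ex.n_classes_averaged + 1

    def test_macro_equals_mean_of_included_per_class(self, rng, scheme):
        pred, gt = random_label_pair(rng, shape=(7, 7, 7), n_classes=8)
        report, _ = evaluate_case(pred, gt, scheme)
        included = [k for k in report.per_class
                    if k != 0 and (report.per_class[k].gt_voxels > 0)]
        manual = np.mean([report.per_class[k].dice for k in included])
        assert report.macro["mDice"] == pytest.approx(manual)

    def test_metrics_invariant_under_joint_permutation(self, rng, scheme):
        pred, gt = random_label_pair(rng, shape=(6, 6, 6), n_classes=5)
        perm = lambda a: np.transpose(a[::-1, :, ::-1], (2, 1, 0))
        rep1, _ = evaluate_case(pred, gt, scheme)
        rep2, _ = evaluate_case(make_lv(perm(pred.labels)),
                                make_lv(perm(gt.labels)), scheme)
        assert rep1.macro == rep2.macro
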