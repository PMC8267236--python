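"""Evaluation indexes: exact arithmetic on enumerable masks, Hausdorff
against a brute-force oracle, invariances, and cross-module consistency."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from aanet.brats_io import RegionTargets, labels_to_regions
from aanet.losses import dice_loss
from aanet.metrics import (ConfusionCounts, confusion_counts, dice_coefficient,
                           evaluate, hausdorff_distance, mask_boundary,
                           precision, region_metrics, sensitivity)


def brute_force_hausdorff(a_mask, b_mask):
    """Max of directed nearest-point distances over boundary pixels."""
    a = np.argwhere(mask_boundary(a_mask)).astype(float)
    b = np.argwhere(mask_boundary(b_mask)).astype(float)
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestConfusion:
    def test_perfect_full_mask(self):
        m = np.ones((3, 3), bool)
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (9, 0, 0, 0)

    def test_pred_full_truth_empty(self):
        c = confusion_counts(np.ones((2, 2), bool), np.zeros((2, 2), bool))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 4, 0, 0)

    def test_four_pixel_enumeration(self):
        c = confusion_counts(np.array([1, 1, 0, 0], bool), np.array([1, 0, 1, 0], bool))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((2, 2), bool), np.zeros((3, 2), bool))


class TestOverlapIndexes:
    def test_balanced_counts_give_half(self):
        c = ConfusionCounts(tp=1, fp=1, fn=1, tn=1)
        assert dice_coefficient(c) == 0.5
        assert precision(c) == 0.5
        assert sensitivity(c) == 0.5

    def test_perfect_nonempty_prediction(self):
        c = ConfusionCounts(tp=5, fp=0, fn=0, tn=3)
        assert dice_coefficient(c) == precision(c) == sensitivity(c) == 1.0

    def test_no_tp_with_fp_gives_zero_precision(self):
        assert precision(ConfusionCounts(tp=0, fp=3, fn=0, tn=1)) == 0.0

    def test_both_empty_scored_perfect(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=9)
        assert dice_coefficient(c) == precision(c) == sensitivity(c) == 1.0


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.uniform(size=(9, 9)) > 0.6
        m[4, 4] = True
        assert hausdorff_distance(m, m) == 0.0

    def test_single_pixels_three_four_five(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0], b[3, 4] = True, True
        assert hausdorff_distance(a, b) == 5.0

    def test_uniform_one_pixel_dilation_gives_one(self):
        from scipy.ndimage import binary_dilation
        truth = np.zeros((9, 9), bool)
        truth[3:6, 3:6] = True
        # 4-neighbor dilation: every boundary point moves out by exactly 1
        pred = binary_dilation(truth)
        assert hausdorff_distance(pred, truth) == 1.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            a = rng.uniform(size=(8, 8)) > 0.5
            b = rng.uniform(size=(8, 8)) > 0.5
            if not (a.any() and b.any()):
                continue
            assert hausdorff_distance(a, b) == pytest.approx(
                brute_force_hausdorff(a, b), abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.uniform(size=(10, 10)) > 0.5
        b = rng.uniform(size=(10, 10)) > 0.5
        assert hausdorff_distance(a, b) == hausdorff_distance(b, a)

    def test_translation_invariance(self):
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[2:5, 2:4], b[3:6, 2:5] = True, True
        base = hausdorff_distance(a, b)
        assert hausdorff_distance(np.roll(a, (3, 4), (0, 1)),
                                  np.roll(b, (3, 4), (0, 1))) == base

    def test_empty_conventions(self):
        empty = np.zeros((10, 10), bool)
        full = np.ones((10, 10), bool)
        assert hausdorff_distance(empty, empty) == 0.0
        assert hausdorff_distance(full, empty) == pytest.approx(np.hypot(10, 10))
        assert hausdorff_distance(full, empty, empty_sentinel=3.0) == 3.0


class TestEvaluate:
    def _targets(self, label):
        return labels_to_regions(label)

    def test_perfect_predictions_score_perfectly(self, rng):
        labels = [rng.choice([0, 1, 2, 4], size=(12, 12)) for _ in range(3)]
        truths = [self._targets(l) for l in labels]
        report = evaluate(truths, truths)
        assert np.allclose(report.table[["dice", "precision", "sensitivity"]], 1.0)
        assert np.allclose(report.table["hausdorff"], 0.0)

    def test_two_slice_average(self):
        """Per-slice Dice of 1.0 and 0.5 averages to 0.75."""
        full = np.full((4, 4), 4)
        truth = labels_to_regions(full)
        half = np.zeros((4, 4), int)
        half[:2] = 4  # Dice vs full = 2*8/(8+16) = 2/3... use explicit counts
        pred2 = RegionTargets.unchecked(*(np.concatenate(
            [np.ones((2, 4), bool), np.zeros((2, 4), bool)]),) * 3)
        c = confusion_counts(pred2.wt, truth.wt)
        expected_half = dice_coefficient(c)
        report = evaluate([truth, pred2], [truth, truth])
        assert report.table.loc["wt", "dice"] == pytest.approx(
            (1.0 + expected_half) / 2)

    def test_single_slice_report_equals_slice_metrics(self, rng):
        label = rng.choice([0, 2, 4], size=(10, 10))
        truth = labels_to_regions(label)
        pred = labels_to_regions(np.where(label == 2, 0, label))
        report = evaluate([pred], [truth])
        direct = region_metrics(pred, truth)
        for region in ("wt", "ct", "et"):
            for index in ("dice", "precision", "sensitivity", "hausdorff"):
                assert report.table.loc[region, index] == pytest.approx(
                    direct[region][index])

    def test_length_mismatch_rejected(self):
        t = labels_to_regions(np.zeros((2, 2), int))
        with pytest.raises(ValueError, match="predictions"):
            evaluate([t], [t, t])

    def test_report_layout_and_means(self, rng):
        label = rng.choice([0, 1, 2, 4], size=(8, 8))
        t = labels_to_regions(label)
        report = evaluate([t], [t])
        frame = report.to_frame()
        assert list(frame.index) == ["wt", "ct", "et", "mean"]
        assert list(frame.columns) == ["dice", "precision", "sensitivity", "hausdorff"]
        assert frame.loc["mean", "dice"] == pytest.approx(
            report.table["dice"].mean())


def test_overlap_metrics_permutation_invariant(rng):
    pred = rng.uniform(size=(6, 6)) > 0.5
    truth = rng.uniform(size=(6, 6)) > 0.5
    perm = rng.permutation(36)
    cp = confusion_counts(pred.reshape(-1)[perm], truth.reshape(-1)[perm])
    c = confusion_counts(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (cp.tp, cp.fp, cp.fn, cp.tn)


def test_dice_metric_agrees_with_one_minus_dice_loss(rng):
    """Cross-module: on binary masks the Dice index equals 1 - dice_loss."""
    pred = (rng.uniform(size=(7, 7)) > 0.4).astype(float)
    truth = (rng.uniform(size=(7, 7)) > 0.6).astype(float)
    c = confusion_counts(pred > 0, truth > 0)
    loss = float(dice_loss(pred, truth, epsilon=1e-12))
    assert dice_coefficient(c) == pytest.approx(1.0 - loss, abs=1e-9)
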