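"""Overlap metric identities, brute-force oracles, and model comparison."""

import numpy as np
import pytest
from scipy import stats

from lumenseg.errors import AlignmentError, InputError
from lumenseg.metrics import (ConfusionCounts, compare_models,
                              confusion_counts, dice_loss, dsc,
                              evaluate_frame, overlay_image, precision,
                              recall, significance_stars, summarize)


def brute_force_counts(pred, truth):
    """Per-pixel loop oracle for the vectorized confusion counts."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif truth[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        truth = np.zeros((8, 8), np.uint8)
        truth.ravel()[rng.choice(64, 10, replace=False)] = 1
        c = confusion_counts(truth, truth)
        assert (c.TP, c.FP, c.FN, c.TN) == (10, 0, 0, 54)

    def test_empty_prediction(self, rng):
        truth = np.zeros((8, 8), np.uint8)
        truth.ravel()[:10] = 1
        c = confusion_counts(np.zeros((8, 8), np.uint8), truth)
        assert c.TP == 0 and c.FN == 10

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(50):
            pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            c = confusion_counts(pred, truth)
            assert (c.TP, c.FP, c.FN, c.TN) == brute_force_counts(pred, truth)

    def test_counts_sum_to_frame_size(self, rng):
        pred = (rng.random((16, 16)) > 0.3).astype(np.uint8)
        truth = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        assert confusion_counts(pred, truth).total == 256

    def test_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            confusion_counts(np.zeros((4, 4), np.uint8),
                             np.zeros((8, 8), np.uint8))

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            ConfusionCounts(-1, 0, 0, 0)


class TestDiceAndFriends:
    def test_perfect_overlap(self):
        assert dice_loss(ConfusionCounts(10, 0, 0, 54)) == 0.0

    def test_disjoint_masks(self):
        assert dice_loss(ConfusionCounts(0, 3, 5, 56)) == 1.0

    def test_worked_case(self):
        c = ConfusionCounts(6, 2, 2, 54)
        assert dice_loss(c) == pytest.approx(0.25)
        assert dsc(c) == pytest.approx(0.75)
        assert precision(c) == pytest.approx(0.75)
        assert recall(c) == pytest.approx(0.75)

    def test_dsc_complements_loss_on_random_counts(self, rng):
        for _ in range(1000):
            tp, fp, fn = rng.integers(0, 100, 3)
            c = ConfusionCounts(int(tp), int(fp), int(fn), 10)
            assert dsc(c) + dice_loss(c) == pytest.approx(1.0, abs=1e-12)

    def test_both_empty_convention(self):
        c = ConfusionCounts(0, 0, 0, 64)
        assert dice_loss(c) == 0.0
        assert dsc(c) == 1.0 and precision(c) == 1.0 and recall(c) == 1.0

    def test_transposition_invariance(self, rng):
        pred = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        truth = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        a = evaluate_frame(pred, truth)
        b = evaluate_frame(pred.T, truth.T)
        assert (a.dsc, a.precision, a.recall) == (b.dsc, b.precision, b.recall)


class TestEvaluateFrame:
    def test_perfect(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        r = evaluate_frame(m, m)
        assert (r.dsc, r.precision, r.recall) == (1.0, 1.0, 1.0)

    def test_empty_prediction_nonempty_truth(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[:2] = 1
        r = evaluate_frame(np.zeros((8, 8), np.uint8), truth)
        assert (r.dsc, r.precision, r.recall) == (0.0, 0.0, 0.0)


class TestCompareModels:
    def test_identical_samples_no_effect(self):
        vals = list(np.linspace(0.1, 0.9, 20))
        res = compare_models({"a": vals, "b": vals})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_hand_ranked_oracle(self):
        # groups {1,2,3} and {101,102,103}: ranks 1..6, R1=6, R2=15
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
        res = compare_models({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        scipy_h, scipy_p = stats.kruskal([1, 2, 3], [101, 102, 103])
        assert res.statistic == pytest.approx(scipy_h)
        assert res.p_value == pytest.approx(scipy_p)

    def test_pairwise_stars(self):
        rng = np.random.default_rng(0)
        a = list(rng.normal(0, 1, 50))
        b = list(rng.normal(5, 1, 50))
        res = compare_models({"a": a, "b": b})
        assert res.pairwise[0].stars == "***"

    def test_too_few_groups(self):
        with pytest.raises(InputError):
            compare_models({"a": [1, 2]})

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""


class TestAggregation:
    def test_summary_mean_and_quartiles(self):
        recs = [evaluate_frame(np.ones((4, 4), np.uint8),
                               np.ones((4, 4), np.uint8), t=t, model_tag="m")
                for t in range(4)]
        s = summarize(recs)["m"]
        assert s["dsc_mean"] == 1.0 and s["dsc_median"] == 1.0
        assert s["n_frames"] == 4

    def test_overlay_colors(self):
        pred = np.array([[1, 1], [0, 0]], np.uint8)
        truth = np.array([[1, 0], [1, 0]], np.uint8)
        img = overlay_image(pred, truth)
        np.testing.assert_array_equal(img[0, 0], [1.0, 1.0, 0.0])   # TP yellow
        np.testing.assert_array_equal(img[1, 1], [0.0, 0.0, 0.0])   # TN black
        assert img[0, 1, 0] > 0.9 and img[0, 1, 2] > 0.5            # FP pink
        np.testing.assert_array_equal(img[1, 0], [0.0, 0.0, 1.0])   # FN blue
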