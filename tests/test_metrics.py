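import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedgerm.metrics import (
    DetectionBox,
    average_precision,
    box_iou,
    count_mae,
    evaluate_detections,
    match_detections,
    mean_ap,
    precision_recall,
    relative_error,
    segmentation_metrics,
)


def _box(x0, y0, x1, y1, label="yes", conf=1.0):
    return DetectionBox(x0, y0, x1, y1, label=label, confidence=conf)


class TestBoxIoU:
    def test_identical(self):
        assert box_iou(_box(0, 0, 10, 10), _box(0, 0, 10, 10)) == 1.0

    def test_disjoint(self):
        assert box_iou(_box(0, 0, 10, 10), _box(20, 20, 30, 30)) == 0.0

    def test_half_overlap_by_hand(self):
        # intersection 50, union 100 + 100 - 50 = 150
        assert box_iou(_box(0, 0, 10, 10), _box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = _box(0, 0, 7, 9), _box(3, 2, 12, 11)
        assert box_iou(a, b) == box_iou(b, a)


class TestMatchDetections:
    def test_perfect_predictions(self):
        truths = [_box(i * 20, 0, i * 20 + 10, 10) for i in range(3)]
        match = match_detections(truths, truths, 0.5)
        assert match.tp["yes"] == 3 and match.fp["yes"] == 0 and match.fn["yes"] == 0

    def test_prediction_claims_best_overlapping_truth(self):
        t1 = _box(0, 0, 10, 10)  # IoU 0.6 region
        t2 = _box(0, 0, 10, 9)
        pred = _box(0, 0, 10, 10)
        # pred overlaps t1 at 1.0 and t2 at 0.9; claims t1, t2 is FN
        match = match_detections([pred], [t1, t2], 0.5)
        assert match.tp["yes"] == 1 and match.fn["yes"] == 1
        assert match.pairs["yes"][0][1] == 0

    def test_iou_equal_to_threshold_is_fp(self):
        truth = _box(0, 0, 10, 10)
        pred = _box(0, 0, 10, 5)  # IoU exactly 0.5
        assert box_iou(pred, truth) == 0.5
        match = match_detections([pred], [truth], 0.5)
        assert match.tp["yes"] == 0 and match.fp["yes"] == 1 and match.fn["yes"] == 1

    def test_classes_matched_independently(self):
        truth = [_box(0, 0, 10, 10, "yes"), _box(0, 0, 10, 10, "no")]
        pred = [_box(0, 0, 10, 10, "no"), _box(0, 0, 10, 10, "yes")]
        match = match_detections(pred, truth, 0.5)
        assert match.tp == {"no": 1, "yes": 1}

    def test_each_truth_claimed_once(self):
        truth = [_box(0, 0, 10, 10)]
        preds = [_box(0, 0, 10, 10, conf=0.9), _box(0, 0, 10, 10, conf=0.8)]
        match = match_detections(preds, truth, 0.5)
        assert match.tp["yes"] == 1 and match.fp["yes"] == 1

    def test_equal_confidence_tiebreak_permutation_invariant(self):
        truths = [_box(0, 0, 10, 10), _box(30, 0, 40, 10)]
        preds = [
            _box(1, 0, 11, 10, conf=0.7),
            _box(29, 0, 39, 10, conf=0.7),
        ]
        results = []
        for perm in itertools.permutations(preds):
            match = match_detections(list(perm), truths, 0.5)
            assignment = sorted(
                (perm[i].x_min, j) for i, j, _ in match.pairs["yes"]
            )
            results.append((match.tp["yes"], assignment))
        assert len(set(map(str, results))) == 1


class TestPrecisionRecall:
    def test_direct_arithmetic(self):
        preds = [_box(i * 20, 0, i * 20 + 10, 10, conf=0.9) for i in range(8)]
        preds += [_box(500 + i * 20, 0, 510 + i * 20, 10, conf=0.8) for i in range(2)]
        truths = [_box(i * 20, 0, i * 20 + 10, 10) for i in range(8)]
        match = match_detections(preds, truths, 0.5)
        p, r, flagged = precision_recall(match)["yes"]
        assert (p, r) == (0.8, 1.0) and not flagged

    def test_degenerate_denominators_flagged(self):
        match = match_detections([], [_box(0, 0, 10, 10)] * 5, 0.5)
        p, r, flagged = precision_recall(match)["yes"]
        assert p == 0.0 and r == 0.0 and flagged

    def test_perfect(self):
        truths = [_box(i * 20, 0, i * 20 + 10, 10) for i in range(5)]
        p, r, flagged = precision_recall(match_detections(truths, truths, 0.5))["yes"]
        assert (p, r) == (1.0, 1.0) and not flagged


def _brute_force_ap(detections, n_truths):
    """Independent oracle: explicit PR points plus a max-over-suffix
    rectangle sum across every distinct recall level."""
    ranked = sorted(detections, key=lambda d: -d[0])
    points = []  # (recall, precision) after each prefix
    tp = fp = 0
    for conf, is_tp in ranked:
        tp, fp = tp + is_tp, fp + (not is_tp)
        points.append((tp / n_truths, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for r in sorted({r for r, _ in points}):
        if r == prev_r:
            continue
        best_p = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_single_correct_top_prediction(self):
        assert average_precision([(0.9, True)], 1) == 1.0

    def test_enumerated_three_prediction_curve(self):
        # ranked (correct, wrong, correct) against 2 truths:
        # envelope gives 1.0 for recall <= 0.5, 2/3 up to 1.0
        detections = [(0.9, True), (0.8, False), (0.7, True)]
        assert average_precision(detections, 2) == pytest.approx(5 / 6)

    def test_all_wrong(self):
        assert average_precision([(0.9, False), (0.5, False)], 3) == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n_truths = int(rng.integers(1, 5))
            n_det = int(rng.integers(0, 7))
            detections = [
                (float(rng.random()), bool(rng.random() < 0.6))
                for _ in range(n_det)
            ]
            # cap TPs at the number of truths (a valid matching never
            # produces more)
            n_tp = sum(1 for _, t in detections if t)
            if n_tp > n_truths:
                detections = [
                    (c, False) if t and (i % 2 == 0) else (c, t)
                    for i, (c, t) in enumerate(detections)
                ]
            ours = average_precision(detections, n_truths)
            oracle = _brute_force_ap(detections, n_truths)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_101_point_close_to_continuous(self):
        detections = [(0.9, True), (0.8, False), (0.7, True), (0.6, True)]
        cont = average_precision(detections, 3)
        grid = average_precision(detections, 3, interpolation="101_point")
        assert abs(cont - grid) < 0.02


class TestAggregates:
    def test_mean_ap(self):
        assert mean_ap({"yes": 1.0, "no": 0.5}) == 0.75
        assert mean_ap({"yes": 0.9}) == 0.9
        assert mean_ap({"a": 0.0, "b": 0.0}) == 0.0

    def test_count_mae_single_image(self):
        ae, mae = count_mae({"yes": [20]}, {"yes": [22]})
        assert ae["yes"] == pytest.approx(0.1) and mae == pytest.approx(0.1)

    def test_count_mae_perfect(self):
        ae, mae = count_mae({"yes": [5, 9], "no": [3, 4]}, {"yes": [5, 9], "no": [3, 4]})
        assert mae == 0.0

    def test_count_mae_two_images(self):
        ae, _ = count_mae({"yes": [10, 20]}, {"yes": [11, 18]})
        assert ae["yes"] == pytest.approx(0.1)

    def test_count_mae_skips_zero_truth_images(self):
        with pytest.warns(UserWarning, match="zero true count"):
            ae, _ = count_mae({"yes": [0, 10]}, {"yes": [2, 11]})
        assert ae["yes"] == pytest.approx(0.1)

    @given(st.lists(st.tuples(st.integers(1, 50), st.integers(0, 50)),
                    min_size=1, max_size=10),
           st.integers(2, 5))
    def test_count_mae_scale_invariant(self, pairs, scale):
        y = [p[0] for p in pairs]
        yp = [p[1] for p in pairs]
        ae1, _ = count_mae({"c": y}, {"c": yp})
        ae2, _ = count_mae({"c": [v * scale for v in y]},
                           {"c": [v * scale for v in yp]})
        assert ae1["c"] == pytest.approx(ae2["c"])


class TestRelativeError:
    @pytest.mark.parametrize(
        "auto,manual,expected",
        [(22, 20, -0.10), (12, 14, 0.14), (25, 24, -0.04), (9, 10, 0.10)],
    )
    def test_signed_convention_reproduces_reported_values(self, auto, manual, expected):
        assert round(relative_error(auto, manual, signed=True), 2) == expected

    def test_absolute_variant(self):
        assert relative_error(22, 20, signed=False) == pytest.approx(0.1)

    def test_equal_counts_zero_both_modes(self):
        assert relative_error(7, 7, signed=True) == 0.0
        assert relative_error(7, 7, signed=False) == 0.0

    def test_zero_manual(self):
        assert relative_error(0, 0) == 0.0
        with pytest.raises(ValueError):
            relative_error(3, 0)


class TestSegmentationMetrics:
    def test_identical_masks(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:6, 2:6] = True
        score = segmentation_metrics(mask, mask)
        assert (score.dice, score.iou, score.pixel_accuracy, score.fpr) == (1, 1, 1, 0)

    def test_hand_confusion_counts(self):
        pred = np.array([[True, True], [False, False]])
        truth = np.array([[True, False], [True, False]])
        score = segmentation_metrics(pred, truth)
        assert (score.tp, score.fp, score.fn, score.tn) == (1, 1, 1, 1)
        assert score.dice == 0.5
        assert score.iou == pytest.approx(1 / 3)
        assert score.pixel_accuracy == 0.5
        assert score.fpr == 0.5

    def test_disjoint_masks(self):
        pred = np.zeros((20, 20), dtype=bool)
        truth = np.zeros((20, 20), dtype=bool)
        pred[:3, :3] = True
        truth[10:13, 10:13] = True
        score = segmentation_metrics(pred, truth)
        assert score.dice == 0.0 and score.iou == 0.0

    def test_vacuous_empty_masks(self):
        empty = np.zeros((4, 4), dtype=bool)
        score = segmentation_metrics(empty, empty)
        assert score.vacuous and score.dice == 1.0 and score.fpr == 0.0

    def test_dice_iou_identity_random_masks(self, rng):
        for _ in range(300):
            pred = rng.random((12, 12)) < rng.random()
            truth = rng.random((12, 12)) < rng.random()
            score = segmentation_metrics(pred, truth)
            assert score.dice == pytest.approx(
                2 * score.iou / (1 + score.iou), abs=1e-12
            )


class TestEvaluateDetections:
    def test_ground_truth_against_itself_is_perfect(self):
        truths = {
            "img1": [_box(0, 0, 10, 10, "yes"), _box(30, 0, 44, 12, "no")],
            "img2": [_box(5, 5, 25, 20, "yes")],
        }
        report = evaluate_detections(truths, truths, 0.5)
        assert report["map"] == 1.0
        assert report["mae"] == 0.0

    def test_missing_class_in_predictions_reported_not_fatal(self):
        truths = {"img": [_box(0, 0, 10, 10, "yes"), _box(30, 0, 40, 10, "no")]}
        preds = {"img": [_box(0, 0, 10, 10, "yes")]}
        report = evaluate_detections(preds, truths, 0.5)
        assert report["classes"]["no"]["fn"] == 1
        assert report["classes"]["no"]["ap"] == 0.0

    def test_empty_predictions_zero_recall(self):
        truths = {"img": [_box(0, 0, 10, 10, "yes")]}
        report = evaluate_detections({}, truths, 0.5)
        assert report["classes"]["yes"]["recall"] == 0.0
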