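"""Detection and segmentation evaluation metrics.

Detection quality is scored by IoU-based matching of predicted to
ground-truth boxes (per class, greedy in confidence order, one truth per
prediction), from which precision, recall, average precision (area under
the precision-envelope/recall curve) and mAP follow. Count agreement is
scored by the per-class mean relative count error (AE) averaged over
classes (MAE), and by per-image relative errors. Mask quality is scored by
the pixel confusion counts and Dice, IoU, pixel accuracy and false positive
rate.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class DetectionBox:
    """An axis-aligned box with class label and confidence.

    Coordinates are pixels, 0-based, half-open: the box covers
    [x_min, x_max) x [y_min, y_max). Ground-truth boxes carry confidence 1.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("box must have positive width and height")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclasses.dataclass
class MatchResult:
    """Per-class TP/FP/FN counts and the matched (pred, truth, IoU) pairs."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    #: per class: list of (prediction index, truth index, IoU)
    pairs: dict[str, list[tuple[int, int, float]]]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))


@dataclasses.dataclass
class SegmentationScore:
    """Pixel confusion counts with Dice/IoU/PA/FPR."""

    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    iou: float
    pixel_accuracy: float
    fpr: float
    vacuous: bool = False


def box_iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    preds: Sequence[DetectionBox],
    truths: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy per-class matching of predictions to ground truth.

    Classes are matched independently. Predictions are visited in
    descending confidence (ties broken by lower x_min, then y_min); each
    claims the not-yet-matched truth of its class with the highest IoU,
    provided that IoU is strictly above the threshold (TP), otherwise it is
    an FP. Truths never claimed are FN.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    classes = sorted({b.label for b in preds} | {b.label for b in truths})
    tp: dict[str, int] = {c: 0 for c in classes}
    fp: dict[str, int] = {c: 0 for c in classes}
    fn: dict[str, int] = {c: 0 for c in classes}
    pairs: dict[str, list[tuple[int, int, float]]] = {c: [] for c in classes}

    for cls in classes:
        p_idx = [i for i, b in enumerate(preds) if b.label == cls]
        t_idx = [i for i, b in enumerate(truths) if b.label == cls]
        p_idx.sort(key=lambda i: (-preds[i].confidence, preds[i].x_min, preds[i].y_min))
        claimed: set[int] = set()
        for i in p_idx:
            best_j, best_iou = -1, 0.0
            for j in t_idx:
                if j in claimed:
                    continue
                iou = box_iou(preds[i], truths[j])
                if iou > best_iou:
                    best_j, best_iou = j, iou
            if best_j >= 0 and best_iou > iou_threshold:
                claimed.add(best_j)
                tp[cls] += 1
                pairs[cls].append((i, best_j, best_iou))
            else:
                fp[cls] += 1
        fn[cls] = len(t_idx) - len(claimed)
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def precision_recall(
    match: MatchResult,
) -> dict[str, tuple[float, float, bool]]:
    """Per-class (precision, recall, degenerate-denominator flag).

    A zero denominator yields 0 for that quantity with the flag set.
    """
    out = {}
    for cls in match.classes:
        tp, fp, fn = match.tp[cls], match.fp[cls], match.fn[cls]
        flagged = (tp + fp == 0) or (tp + fn == 0)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        out[cls] = (p, r, flagged)
    return out


def average_precision(
    detections: Sequence[tuple[float, bool]],
    n_truths: int,
    interpolation: str = "all_points",
) -> float:
    """Area under the precision-envelope vs recall curve for one class.

    ``detections`` are (confidence, is_true_positive) pairs; ``n_truths``
    is the class's ground-truth count. Detections are ranked by descending
    confidence, precision is monotonized from the right (the envelope), and
    the envelope is integrated over recall — the continuous "all-points"
    method. ``interpolation="101_point"`` instead averages the envelope
    sampled at recalls 0.00, 0.01, ..., 1.00.
    """
    if n_truths < 1:
        raise ValueError("AP undefined without ground-truth instances")
    if interpolation not in ("all_points", "101_point"):
        raise ValueError("interpolation must be 'all_points' or '101_point'")
    if len(detections) == 0:
        return 0.0
    order = sorted(range(len(detections)), key=lambda i: -detections[i][0])
    tps = np.array([bool(detections[i][1]) for i in order])
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(~tps)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / n_truths
    # right-to-left running maximum: the precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101_point":
        grid = np.linspace(0.0, 1.0, 101)
        # envelope value at recall >= g (0 beyond the last achieved recall)
        vals = [envelope[recall >= g][0] if np.any(recall >= g) else 0.0 for g in grid]
        return float(np.mean(vals))
    # integrate: rectangles between distinct recall levels
    prev_recall = 0.0
    ap = 0.0
    for k in range(len(recall)):
        if tps[k]:
            ap += (recall[k] - prev_recall) * envelope[k]
            prev_recall = recall[k]
    return float(ap)


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if not per_class_ap:
        raise ValueError("need at least one class with defined AP")
    return float(np.mean(list(per_class_ap.values())))


def count_mae(
    true_counts: Mapping[str, Sequence[float]],
    pred_counts: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Per-class mean relative count error (AE) and their mean (MAE).

    For each class, AE is the mean over images of |y_i - y_i'| / y_i.
    Images with y_i = 0 are skipped for that class with a warning (the
    relative error is undefined there); a class with no valid images is
    excluded from the MAE with a warning.
    """
    ae: dict[str, float] = {}
    for cls in true_counts:
        y = np.asarray(true_counts[cls], dtype=float)
        yp = np.asarray(pred_counts[cls], dtype=float)
        if y.shape != yp.shape:
            raise ValueError(f"class {cls!r}: count vectors differ in length")
        valid = y != 0
        if not np.all(valid):
            warnings.warn(
                f"class {cls!r}: skipping {int((~valid).sum())} image(s) with "
                "zero true count",
                stacklevel=2,
            )
        if not valid.any():
            warnings.warn(f"class {cls!r}: AE undefined, excluded", stacklevel=2)
            continue
        ae[cls] = float(np.mean(np.abs(y[valid] - yp[valid]) / y[valid]))
    if not ae:
        raise ValueError("AE undefined for every class")
    return ae, float(np.mean(list(ae.values())))


def relative_error(auto: float, manual: float, signed: bool = True) -> float:
    """Relative count error against the manual (ground-truth) value.

    Signed mode returns (manual - auto) / manual, matching the reporting
    convention where over-counting is negative; absolute mode returns
    |auto - manual| / manual. Values are returned at full precision;
    rounding (2 d.p.) is a reporting concern.
    """
    if manual == 0:
        if auto == 0:
            return 0.0
        raise ValueError("relative error undefined: manual count is 0")
    if signed:
        return (manual - auto) / manual
    return abs(auto - manual) / manual


def segmentation_metrics(
    pred_mask: np.ndarray, truth_mask: np.ndarray
) -> SegmentationScore:
    """Pixel confusion counts and Dice / IoU / PA / FPR for two masks.

    An empty truth with an empty prediction is scored as vacuously perfect
    (Dice = IoU = PA = 1, FPR = 0) with the ``vacuous`` flag set.
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must have the same shape")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    total = tp + fp + fn + tn

    if tp + fp + fn == 0:
        return SegmentationScore(
            tp=tp, fp=fp, fn=fn, tn=tn,
            dice=1.0, iou=1.0, pixel_accuracy=1.0, fpr=0.0, vacuous=True,
        )
    dice = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    pa = (tp + tn) / total
    fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
    return SegmentationScore(
        tp=tp, fp=fp, fn=fn, tn=tn,
        dice=dice, iou=iou, pixel_accuracy=pa, fpr=fpr,
    )


def evaluate_detections(
    preds_by_image: Mapping[str, Sequence[DetectionBox]],
    truths_by_image: Mapping[str, Sequence[DetectionBox]],
    iou_threshold: float = 0.5,
) -> dict:
    """Full detection report over a set of images.

    Computes per-class precision/recall (from pooled TP/FP/FN), per-class
    AP over the pooled ranked detections, mAP, per-class AE over per-image
    counts and the MAE. Images present only in the truth mapping count as
    having no predictions.
    """
    images = sorted(set(preds_by_image) | set(truths_by_image))
    classes = sorted(
        {b.label for boxes in truths_by_image.values() for b in boxes}
        | {b.label for boxes in preds_by_image.values() for b in boxes}
    )
    pooled: dict[str, list[tuple[float, bool]]] = {c: [] for c in classes}
    n_truths = {c: 0 for c in classes}
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    true_counts: dict[str, list[int]] = {c: [] for c in classes}
    pred_counts: dict[str, list[int]] = {c: [] for c in classes}

    for image in images:
        preds = list(preds_by_image.get(image, ()))
        truths = list(truths_by_image.get(image, ()))
        match = match_detections(preds, truths, iou_threshold)
        matched_pred_idx = {
            c: {i for i, _, _ in match.pairs.get(c, [])} for c in match.classes
        }
        for c in match.classes:
            tp[c] += match.tp[c]
            fp[c] += match.fp[c]
            fn[c] += match.fn[c]
        for i, b in enumerate(preds):
            pooled[b.label].append(
                (b.confidence, i in matched_pred_idx.get(b.label, set()))
            )
        for c in classes:
            n_truths[c] += sum(1 for b in truths if b.label == c)
            true_counts[c].append(sum(1 for b in truths if b.label == c))
            pred_counts[c].append(sum(1 for b in preds if b.label == c))

    report: dict = {"iou_threshold": iou_threshold, "classes": {}, "n_images": len(images)}
    aps = {}
    for c in classes:
        denom_p = tp[c] + fp[c]
        denom_r = tp[c] + fn[c]
        cls_report = {
            "tp": tp[c], "fp": fp[c], "fn": fn[c],
            "precision": tp[c] / denom_p if denom_p else 0.0,
            "recall": tp[c] / denom_r if denom_r else 0.0,
        }
        if n_truths[c] > 0:
            aps[c] = average_precision(pooled[c], n_truths[c])
            cls_report["ap"] = aps[c]
        else:
            warnings.warn(f"class {c!r}: no ground truth, AP undefined", stacklevel=2)
        report["classes"][c] = cls_report
    if aps:
        report["map"] = mean_ap(aps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ae, mae = count_mae(true_counts, pred_counts)
            report["ae"] = ae
            report["mae"] = mae
        except ValueError:
            pass
    return report


def map_sweep(
    preds_by_image: Mapping[str, Sequence[DetectionBox]],
    truths_by_image: Mapping[str, Sequence[DetectionBox]],
    thresholds: Sequence[float] = tuple(np.arange(0.5, 0.96, 0.05)),
) -> float:
    """Convenience mAP averaged over an IoU-threshold sweep (0.5:0.05:0.95).

    A plain mean of single-threshold mAPs, not a full COCO evaluator.
    """
    maps = []
    for t in thresholds:
        report = evaluate_detections(preds_by_image, truths_by_image, float(t))
        maps.append(report.get("map", 0.0))
    return float(np.mean(maps))
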