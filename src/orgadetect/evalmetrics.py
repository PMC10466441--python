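"""VOC-style detection evaluation: greedy matching, AP, mAP, precision/recall/F1.

AP uses all-point interpolation (the VOC2010+ convention: the precision
envelope is made monotone non-increasing and integrated over recall
increments) by default; the 11-point VOC2007 convention is available via
``interpolation="11point"``. Every report records which was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .boxes import BoundingBox, iou

__all__ = ["EvalReport", "match_detections", "average_precision", "f1_score", "evaluate"]


@dataclass
class EvalReport:
    per_class_ap: dict[str, float]
    map_score: float
    precision: float
    recall: float
    f1: float
    iou_threshold: float
    confidence_threshold: float
    interpolation: str = "allpoint"
    undefined_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": dict(self.per_class_ap),
            "map": self.map_score,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "iou_threshold": self.iou_threshold,
            "confidence_threshold": self.confidence_threshold,
            "interpolation": self.interpolation,
            "undefined_classes": list(self.undefined_classes),
        }


def match_detections(
    detections: Sequence[BoundingBox],
    ground_truth: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Label single-image, single-class detections TP/FP by greedy VOC matching.

    Detections are visited in confidence-descending order; each may claim at
    most one still-unmatched truth of IoU >= ``iou_threshold`` (the best one).
    Returns (per-detection TP flags, aligned with the input order) and the
    count of unmatched truths (FN).
    """
    order = sorted(range(len(detections)), key=lambda i: -(detections[i].confidence or 0.0))
    matched = [False] * len(ground_truth)
    tp = [False] * len(detections)
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(ground_truth):
            if matched[j] or g.label != detections[i].label:
                continue
            v = iou(detections[i], g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[i] = True
    fn = sum(1 for j, g in enumerate(ground_truth) if not matched[j])
    return tp, fn


def average_precision(
    tp_sequence: Sequence[bool], num_truths: int, interpolation: str = "allpoint"
) -> float:
    """Area under the precision-recall curve for one class.

    ``tp_sequence`` must already be sorted by confidence descending (pooled
    over the test set).
    """
    if num_truths == 0:
        raise ValueError("AP undefined for a class with zero ground-truth boxes")
    if len(tp_sequence) == 0:
        return 0.0
    tp = np.asarray(tp_sequence, dtype=float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / num_truths
    precision = cum_tp / (cum_tp + cum_fp)
    if interpolation == "11point":
        ap = 0.0
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r - 1e-12
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)
    if interpolation != "allpoint":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # monotone non-increasing precision envelope, integrated over recall steps
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(
    detections_by_image: Mapping[str, Sequence[BoundingBox]],
    truths_by_image: Mapping[str, Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.5,
    interpolation: str = "allpoint",
) -> EvalReport:
    """Pooled test-set evaluation.

    AP per class is computed over all detections regardless of the confidence
    threshold (the PR curve sweeps it); precision/recall/F1 are point metrics
    counting only detections with confidence >= ``confidence_threshold``.
    A class detected but absent from the truths gets an undefined AP: it is
    excluded from mAP with a warning and listed in ``undefined_classes``.
    """
    classes = sorted(
        {b.label for bs in truths_by_image.values() for b in bs}
        | {b.label for bs in detections_by_image.values() for b in bs}
    )
    image_ids = sorted(set(detections_by_image) | set(truths_by_image))

    per_class_ap: dict[str, float] = {}
    undefined: list[str] = []
    tp_pt = fp_pt = fn_pt = 0
    for cls in classes:
        scored: list[tuple[float, bool]] = []  # (confidence, is_tp)
        n_truths = 0
        for img in image_ids:
            dets = [b for b in detections_by_image.get(img, []) if b.label == cls]
            gts = [b for b in truths_by_image.get(img, []) if b.label == cls]
            n_truths += len(gts)
            tp_flags, _ = match_detections(dets, gts, iou_threshold)
            for b, is_tp in zip(dets, tp_flags):
                scored.append((b.confidence or 0.0, is_tp))
            # point metrics at the confidence threshold
            dets_thr = [b for b in dets if (b.confidence or 0.0) >= confidence_threshold]
            tp_thr, fn_thr = match_detections(dets_thr, gts, iou_threshold)
            tp_pt += sum(tp_thr)
            fp_pt += len(tp_thr) - sum(tp_thr)
            fn_pt += fn_thr
        scored.sort(key=lambda t: -t[0])
        if n_truths == 0:
            if scored:
                warnings.warn(f"class {cls!r} has detections but no ground truth; AP undefined")
                undefined.append(cls)
            continue
        per_class_ap[cls] = average_precision([s[1] for s in scored], n_truths, interpolation)

    map_score = float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0
    precision = tp_pt / (tp_pt + fp_pt) if tp_pt + fp_pt else 0.0
    recall = tp_pt / (tp_pt + fn_pt) if tp_pt + fn_pt else 0.0
    return EvalReport(
        per_class_ap=per_class_ap,
        map_score=map_score,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        iou_threshold=iou_threshold,
        confidence_threshold=confidence_threshold,
        interpolation=interpolation,
        undefined_classes=undefined,
    )
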