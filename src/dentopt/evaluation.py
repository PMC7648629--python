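"""Detection-quality metrics: IOU matching, precision/recall/F1, AP and mAP.

A detection is a true positive when it can be matched to a same-class
ground-truth box with intersection-over-union at or above the threshold
(default 0.5); each ground-truth box may absorb at most one detection, so
duplicate detections of an already-matched tooth count as false positives.
Dataset-level precision/recall/F1 pool the TP/FP/FN counts over all images
and tooth classes (micro-averaging); average precision is computed per
tooth class from the confidence-ranked detection outcomes and
macro-averaged into mAP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import BoundingBox, Candidate, N_TEETH, ValidationError

__all__ = [
    "MatchOutcome",
    "EvalReport",
    "iou",
    "match_image",
    "precision_recall",
    "f1",
    "average_precision",
    "evaluate_dataset",
    "evaluate_folds",
    "write_report",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class MatchOutcome:
    """Per-image (or pooled) matching result at a fixed IOU threshold."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    #: (detection, matched ground-truth box or None, IOU of the match or 0)
    matched_pairs: list[tuple[Candidate, BoundingBox | None, float]] = field(default_factory=list)

    def __iadd__(self, other: "MatchOutcome") -> "MatchOutcome":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.matched_pairs.extend(other.matched_pairs)
        return self


def match_image(
    dets: Sequence[Candidate],
    gts: Sequence[tuple[int, BoundingBox]],
    threshold: float = 0.5,
) -> MatchOutcome:
    """Greedily match detections to same-class ground-truth boxes.

    Within each tooth class, detections are taken in descending confidence
    order; each claims the still-unmatched ground-truth box with the highest
    IOU, provided that IOU reaches the threshold.  Leftover detections are
    false positives, leftover ground truths false negatives.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"IOU threshold must lie in (0, 1], got {threshold}")
    out = MatchOutcome()
    by_class_gt: dict[int, list[BoundingBox]] = {}
    for tooth, box in gts:
        by_class_gt.setdefault(tooth, []).append(box)
    by_class_det: dict[int, list[Candidate]] = {}
    for d in dets:
        if d.is_missing:
            continue
        by_class_det.setdefault(d.tooth, []).append(d)

    for tooth in sorted(set(by_class_gt) | set(by_class_det)):
        gt_boxes = by_class_gt.get(tooth, [])
        taken = [False] * len(gt_boxes)
        ranked = sorted(by_class_det.get(tooth, []), key=lambda d: -d.confidence)
        for det in ranked:
            best_i, best_iou = -1, 0.0
            for i, g in enumerate(gt_boxes):
                if taken[i]:
                    continue
                v = iou(det.box, g)
                if v > best_iou:
                    best_i, best_iou = i, v
            if best_i >= 0 and best_iou >= threshold:
                taken[best_i] = True
                out.tp += 1
                out.matched_pairs.append((det, gt_boxes[best_i], best_iou))
            else:
                out.fp += 1
                out.matched_pairs.append((det, None, 0.0))
        out.fn += taken.count(False)
    return out


def precision_recall(m: MatchOutcome) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); a 0/0 ratio is reported as 0 with a warning."""
    if m.tp + m.fp == 0:
        warnings.warn("no detections: precision undefined, reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    if m.tp + m.fn == 0:
        warnings.warn("no ground truths: recall undefined, reported as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = m.tp / (m.tp + m.fn)
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    outcomes: Sequence[tuple[float, bool]],
    n_gt: int,
    style: str = "all_point",
) -> float:
    """Area under the precision-recall curve for one tooth class.

    ``outcomes`` holds (confidence, is_true_positive) for every detection of
    the class across the dataset; ``n_gt`` is the number of ground-truth
    boxes.  ``style`` is ``"all_point"`` (exact area under the interpolated
    precision envelope) or ``"11_point"`` (mean of the envelope at recalls
    0, 0.1, ..., 1.0).
    """
    if style not in ("all_point", "11_point"):
        raise ValueError(f"unknown AP style {style!r}")
    if n_gt <= 0:
        raise ValueError("average precision undefined for a class with no ground truths")
    if not outcomes:
        return 0.0

    order = np.argsort([-conf for conf, _ in outcomes], kind="stable")
    tp = np.array([bool(outcomes[i][1]) for i in order], dtype=float)
    cum_tp = np.cumsum(tp)
    cum_det = np.arange(1, len(tp) + 1)
    precision = cum_tp / cum_det
    recall = cum_tp / n_gt

    # Precision envelope: running max from the right.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if style == "11_point":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r - 1e-12
            pts.append(float(env[mask][0]) if mask.any() else 0.0)
        return float(np.mean(pts))
    # all-point: sum of envelope precision over recall increments
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * env))


@dataclass
class EvalReport:
    """Aggregate metrics over a dataset (or one fold of it)."""

    per_class_ap: dict[int, float]
    map: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    n_images: int

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mAP": self.map,
            "per_class_ap": {str(k): v for k, v in sorted(self.per_class_ap.items())},
        }


GroundTruth = Mapping[str, Mapping[int, BoundingBox]]
Detections = Mapping[str, Sequence[Candidate]]


def evaluate_dataset(
    detections: Detections,
    ground_truth: GroundTruth,
    iou_threshold: float = 0.5,
    ap_style: str = "all_point",
) -> EvalReport:
    """Match every image and pool the outcomes into one report.

    ``detections`` maps image id to a detection list (raw candidates or the
    non-missing assignments of an optimized pattern); ``ground_truth`` maps
    image id to a tooth -> box mapping.  The two must cover the same images.
    """
    orphans = set(detections) ^ set(ground_truth)
    if orphans:
        raise ValidationError(
            "image ids do not match between detections and ground truth: "
            + ", ".join(sorted(map(str, orphans))[:10])
        )

    pooled = MatchOutcome()
    class_outcomes: dict[int, list[tuple[float, bool]]] = {x: [] for x in range(1, N_TEETH + 1)}
    class_gt_counts = {x: 0 for x in range(1, N_TEETH + 1)}

    for image_id in sorted(ground_truth):
        gts = [(tooth, box) for tooth, box in ground_truth[image_id].items()]
        dets = [d for d in detections[image_id] if not d.is_missing]
        m = match_image(dets, gts, threshold=iou_threshold)
        pooled += m
        for tooth, _ in gts:
            class_gt_counts[tooth] += 1
        for det, gt_box, _ in m.matched_pairs:
            class_outcomes[det.tooth].append((det.confidence, gt_box is not None))

    per_class_ap: dict[int, float] = {}
    skipped = []
    for x in range(1, N_TEETH + 1):
        if class_gt_counts[x] == 0:
            skipped.append(x)
            continue
        per_class_ap[x] = average_precision(class_outcomes[x], class_gt_counts[x], style=ap_style)
    if skipped:
        warnings.warn(
            f"classes without ground truth excluded from mAP: {skipped}", stacklevel=2
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision_recall(pooled)
    return EvalReport(
        per_class_ap=per_class_ap,
        map=float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0,
        precision=p,
        recall=r,
        f1=f1(p, r),
        tp=pooled.tp,
        fp=pooled.fp,
        fn=pooled.fn,
        n_images=len(ground_truth),
    )


def evaluate_folds(
    detections: Detections,
    ground_truth: GroundTruth,
    folds: Mapping[str, Iterable[str]],
    iou_threshold: float = 0.5,
    ap_style: str = "all_point",
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Evaluate disjoint image folds separately and tabulate per-fold metrics.

    Returns the per-fold reports plus a summary table with one row per fold
    and mean/min/max rows over folds, in the style of a K-fold
    cross-validation report.
    """
    reports: dict[str, EvalReport] = {}
    for name, ids in folds.items():
        ids = list(ids)
        reports[name] = evaluate_dataset(
            {i: detections[i] for i in ids},
            {i: ground_truth[i] for i in ids},
            iou_threshold=iou_threshold,
            ap_style=ap_style,
        )
    rows = {
        name: {
            "n_images": r.n_images,
            "n_teeth": r.tp + r.fn,
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
            "mAP": r.map,
        }
        for name, r in reports.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    metric_cols = ["precision", "recall", "f1", "mAP"]
    summary = pd.DataFrame(
        {
            "mean": table[metric_cols].mean(),
            "min": table[metric_cols].min(),
            "max": table[metric_cols].max(),
        }
    ).T
    summary["n_images"] = table["n_images"].sum()
    summary["n_teeth"] = table["n_teeth"].sum()
    table = pd.concat([table, summary])
    return reports, table


def write_report(report: EvalReport, out_dir: str | Path, prefix: str = "eval") -> None:
    """Write a report as JSON plus a per-class AP CSV table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{prefix}_summary.json").write_text(json.dumps(report.to_dict(), indent=2))
    ap_table = pd.DataFrame(
        {
            "tooth": sorted(report.per_class_ap),
            "ap": [report.per_class_ap[x] for x in sorted(report.per_class_ap)],
        }
    )
    ap_table.to_csv(out_dir / f"{prefix}_per_class_ap.csv", index=False)
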