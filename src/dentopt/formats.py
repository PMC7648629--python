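"""File formats and run configuration.

Two interchange formats are supported for both detections and ground truth:

* COCO-style JSON — detections as a result array
  ``[{image_id, category_id, bbox [x, y, width, height], score}, ...]`` and
  ground truth as an annotation file with ``images``/``annotations``/
  ``categories`` sections.  ``category_id`` is the UTN tooth position 1-32,
  and boxes use the COCO ``[x, y, w, h]`` convention.
* CSV — corner-form boxes with documented headers
  (``image_id,tooth,x_min,y_min,x_max,y_max[,confidence]``), convenient for
  hand-built fixtures.

All readers validate records and report offending line/record locators.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .model import BoundingBox, Candidate, CandidateSet, ValidationError, index_candidates
from .scoring import DeltaParams, Weights

__all__ = [
    "RunConfig",
    "read_detections",
    "write_detections",
    "read_ground_truth",
    "write_ground_truth",
]

DET_CSV_COLUMNS = ["image_id", "tooth", "x_min", "y_min", "x_max", "y_max", "confidence"]
GT_CSV_COLUMNS = ["image_id", "tooth", "x_min", "y_min", "x_max", "y_max"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run; serializes to YAML."""

    delta: DeltaParams = DeltaParams()
    weights: Weights = Weights()
    missing_conf: float = 0.35
    sweep_mode: str = "immediate"
    iou_threshold: float = 0.5
    ap_style: str = "all_point"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta"]["near"] = list(self.delta.near)
        d["delta"]["far"] = list(self.delta.far)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "delta" in d:
            dd = dict(d["delta"])
            for key in ("near", "far"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["delta"] = DeltaParams(**dd)
        if "weights" in d:
            d["weights"] = Weights(**d["weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.suffix.lower() == ".json":
        return "coco"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from {path.name}; pass format='coco' or 'csv'")


# ---------------------------------------------------------------- detections

def read_detections(path: str | Path, format: str | None = None) -> dict[str, CandidateSet]:
    """Read per-image detections into confidence-indexed candidate sets."""
    path = Path(path)
    fmt = _infer_format(path, format)
    raw: dict[str, list[tuple[int, BoundingBox, float]]] = {}
    problems: list[str] = []

    if fmt == "coco":
        data = json.loads(path.read_text() or "[]")
        if not data:
            warnings.warn(f"{path}: no detection records", stacklevel=2)
        for i, rec in enumerate(data):
            try:
                tooth = int(rec["category_id"])
                x, y, w, h = rec["bbox"]
                box = BoundingBox.from_xywh(float(x), float(y), float(w), float(h))
                conf = float(rec["score"])
                if not 1 <= tooth <= 32:
                    raise ValidationError(f"category_id {tooth} outside 1..32")
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(f"score {conf} outside [0, 1]")
                raw.setdefault(str(rec["image_id"]), []).append((tooth, box, conf))
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"record {i}: {exc}")
    else:
        df = pd.read_csv(path)
        missing_cols = set(DET_CSV_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
        if df.empty:
            warnings.warn(f"{path}: no detection records", stacklevel=2)
        for i, row in df.iterrows():
            try:
                tooth = int(row["tooth"])
                box = BoundingBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"])
                conf = float(row["confidence"])
                if not 1 <= tooth <= 32:
                    raise ValidationError(f"tooth {tooth} outside 1..32")
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(f"confidence {conf} outside [0, 1]")
                raw.setdefault(str(row["image_id"]), []).append((tooth, box, conf))
            except (TypeError, ValueError) as exc:
                problems.append(f"row {i}: {exc}")

    if problems:
        raise ValidationError(f"{path}: invalid records:\n  " + "\n  ".join(problems))
    return {img: index_candidates(recs, image_id=img) for img, recs in sorted(raw.items())}


def write_detections(
    detections: Mapping[str, Sequence[Candidate]] | Mapping[str, CandidateSet],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write detections (candidate lists or sets, missing entries skipped)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = []
    for image_id in sorted(detections):
        dets = detections[image_id]
        if isinstance(dets, CandidateSet):
            dets = dets.detections()
        for d in dets:
            if d.is_missing:
                continue
            rows.append((str(image_id), d.tooth, d.box, d.confidence))

    if fmt == "coco":
        out = [
            {
                "image_id": image_id,
                "category_id": tooth,
                "bbox": list(box.as_xywh()),
                "score": conf,
            }
            for image_id, tooth, box, conf in rows
        ]
        path.write_text(json.dumps(out, indent=2))
    else:
        df = pd.DataFrame(
            [
                (image_id, tooth, box.x_min, box.y_min, box.x_max, box.y_max, conf)
                for image_id, tooth, box, conf in rows
            ],
            columns=DET_CSV_COLUMNS,
        )
        df.to_csv(path, index=False)


# -------------------------------------------------------------- ground truth

def read_ground_truth(path: str | Path, format: str | None = None) -> dict[str, dict[int, BoundingBox]]:
    """Read ground-truth boxes; at most one box per (image, tooth)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    gt: dict[str, dict[int, BoundingBox]] = {}
    problems: list[str] = []

    def _add(image_id: str, tooth: int, box: BoundingBox, where: str) -> None:
        if not 1 <= tooth <= 32:
            problems.append(f"{where}: tooth {tooth} outside 1..32")
            return
        per_img = gt.setdefault(image_id, {})
        if tooth in per_img:
            problems.append(f"{where}: duplicate box for image {image_id} tooth {tooth}")
            return
        per_img[tooth] = box

    if fmt == "coco":
        data = json.loads(path.read_text() or "{}")
        for img in data.get("images", []):
            gt.setdefault(str(img["id"]), {})
        for i, ann in enumerate(data.get("annotations", [])):
            try:
                x, y, w, h = ann["bbox"]
                box = BoundingBox.from_xywh(float(x), float(y), float(w), float(h))
                _add(str(ann["image_id"]), int(ann["category_id"]), box, f"annotation {i}")
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"annotation {i}: {exc}")
    else:
        df = pd.read_csv(path)
        missing_cols = set(GT_CSV_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
        for i, row in df.iterrows():
            try:
                box = BoundingBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"])
                _add(str(row["image_id"]), int(row["tooth"]), box, f"row {i}")
            except (TypeError, ValueError) as exc:
                problems.append(f"row {i}: {exc}")

    if problems:
        raise ValidationError(f"{path}: invalid ground truth:\n  " + "\n  ".join(problems))
    if not gt:
        warnings.warn(f"{path}: no ground-truth records", stacklevel=2)
    return dict(sorted(gt.items()))


def write_ground_truth(
    gt: Mapping[str, Mapping[int, BoundingBox]],
    path: str | Path,
    format: str | None = None,
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "coco":
        images = [{"id": str(img), "file_name": f"{img}.jpg"} for img in sorted(gt)]
        annotations = []
        ann_id = 1
        for img in sorted(gt):
            for tooth in sorted(gt[img]):
                annotations.append(
                    {
                        "id": ann_id,
                        "image_id": str(img),
                        "category_id": tooth,
                        "bbox": list(gt[img][tooth].as_xywh()),
                        "iscrowd": 0,
                        "area": gt[img][tooth].area,
                    }
                )
                ann_id += 1
        categories = [{"id": x, "name": f"T{x}"} for x in range(1, 33)]
        path.write_text(
            json.dumps(
                {"images": images, "annotations": annotations, "categories": categories},
                indent=2,
            )
        )
    else:
        rows = [
            (str(img), tooth, b.x_min, b.y_min, b.x_max, b.y_max)
            for img in sorted(gt)
            for tooth, b in sorted(gt[img].items())
        ]
        pd.DataFrame(rows, columns=GT_CSV_COLUMNS).to_csv(path, index=False)
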