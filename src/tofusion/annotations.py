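"""Axis-aligned bounding-box annotations and the two interchange formats.

Detection classes follow the neonatal monitoring task: head, nose, torso
and intervention (a caregiver's hand or instrument entering the scene).
Boxes travel either as YOLO text (one ``class cx cy w h`` line per object,
center/size normalized to image dimensions) or as a minimal COCO JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import InvalidParameterError

__all__ = [
    "CLASS_NAMES",
    "BBox",
    "read_yolo_txt",
    "write_yolo_txt",
    "read_coco_json",
    "write_coco_json",
]

CLASS_NAMES = ("head", "nose", "torso", "intervention")


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in pixel coordinates, ``x_min < x_max``, ``y_min < y_max``."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidParameterError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InvalidParameterError("confidence must lie in [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clipped(self, width: float, height: float) -> "BBox | None":
        """Clip to image bounds; None if nothing remains."""
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def intersection_area(self, other: "BBox") -> float:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return max(w, 0.0) * max(h, 0.0)


def write_yolo_txt(boxes, path, width: int, height: int,
                   classes=CLASS_NAMES) -> None:
    """Write boxes in YOLO text format (normalized center/size)."""
    lines = []
    for b in boxes:
        cx, cy = b.center
        lines.append(
            f"{classes.index(b.label)} {cx / width:.6f} {cy / height:.6f} "
            f"{b.width / width:.6f} {b.height / height:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path, width: int, height: int, classes=CLASS_NAMES) -> list[BBox]:
    """Read YOLO text annotations back into pixel-space boxes."""
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        boxes.append(
            BBox(
                label=classes[cls],
                x_min=(cx - w / 2) * width,
                y_min=(cy - h / 2) * height,
                x_max=(cx + w / 2) * width,
                y_max=(cy + h / 2) * height,
                confidence=float(parts[5]) if len(parts) > 5 else None,
            )
        )
    return boxes


def write_coco_json(frames: dict, path, classes=CLASS_NAMES) -> None:
    """Write a minimal COCO-style JSON.

    ``frames`` maps image file name -> (width, height, list of BBox).
    """
    images, annotations = [], []
    ann_id = 1
    for img_id, (name, (w, h, boxes)) in enumerate(sorted(frames.items()), start=1):
        images.append({"id": img_id, "file_name": name, "width": w, "height": h})
        for b in boxes:
            ann = {
                "id": ann_id,
                "image_id": img_id,
                "category_id": classes.index(b.label) + 1,
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "area": b.area,
                "iscrowd": 0,
            }
            if b.confidence is not None:
                ann["score"] = b.confidence
            annotations.append(ann)
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i + 1, "name": c} for i, c in enumerate(classes)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_json(path, classes=CLASS_NAMES) -> dict:
    """Read a COCO JSON into ``{file_name: (width, height, [BBox, ...])}``."""
    doc = json.loads(Path(path).read_text())
    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    imgs = {im["id"]: im for im in doc["images"]}
    out = {
        im["file_name"]: (im["width"], im["height"], [])
        for im in doc["images"]
    }
    for ann in doc["annotations"]:
        im = imgs[ann["image_id"]]
        x, y, w, h = ann["bbox"]
        label = cat_names.get(ann["category_id"], classes[ann["category_id"] - 1])
        out[im["file_name"]][2].append(
            BBox(
                label=label,
                x_min=x,
                y_min=y,
                x_max=x + w,
                y_max=y + h,
                confidence=ann.get("score"),
            )
        )
    return out
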