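"""Canonical box/detection data model and COCO-JSON / CSV readers and writers.

Coordinate convention: continuous corner form ``(x_min, y_min, x_max, y_max)``,
origin at the top-left of the image, no pixel-centre offset.  COCO's
``[x, y, width, height]`` boxes are converted on read and restored on write,
so the two dialects round-trip exactly on rational coordinates.

Boxes can live either in pixel units or normalized to the unit square
(``normalized=True``); fusion operates on normalized coordinates, evaluation
is unit-agnostic as long as detections and ground truth agree.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable

logger = logging.getLogger("fusedet")

ImageId = Hashable


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with a flag recording its coordinate scale.

    Invariants: ``x_min < x_max``, ``y_min < y_max``; if ``normalized`` all
    four coordinates lie in [0, 1].
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.normalized:
            for v in (self.x_min, self.y_min, self.x_max, self.y_max):
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"normalized box coordinate {v} outside [0, 1]"
                    )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)

    @classmethod
    def from_xywh(
        cls, x: float, y: float, w: float, h: float, normalized: bool = False
    ) -> "Box":
        return cls(x, y, x + w, y + h, normalized=normalized)


@dataclass(frozen=True)
class Detection:
    """One scored, labelled box emitted by one model on one image."""

    image_id: ImageId
    box: Box
    score: float
    category_id: int
    model_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"confidence {self.score} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruthBox:
    image_id: ImageId
    box: Box
    category_id: int


@dataclass(frozen=True)
class ImageInfo:
    image_id: ImageId
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"image {self.image_id!r} has non-positive size "
                f"{self.width}x{self.height}"
            )


@dataclass
class Dataset:
    """Images, their ground-truth boxes, and the category vocabulary."""

    images: list[ImageInfo]
    ground_truth: list[GroundTruthBox]
    categories: dict[int, str] = field(default_factory=lambda: {1: "object"})

    def __post_init__(self) -> None:
        known = {im.image_id for im in self.images}
        for gt in self.ground_truth:
            if gt.image_id not in known:
                raise ValidationError(
                    f"ground-truth box references unknown image {gt.image_id!r}"
                )

    @property
    def image_ids(self) -> list[ImageId]:
        return [im.image_id for im in self.images]

    def image_size(self, image_id: ImageId) -> tuple[int, int]:
        for im in self.images:
            if im.image_id == image_id:
                return im.width, im.height
        raise KeyError(image_id)

    def sizes(self) -> dict[ImageId, tuple[int, int]]:
        return {im.image_id: (im.width, im.height) for im in self.images}

    def gt_by_image(self) -> dict[ImageId, list[GroundTruthBox]]:
        out: dict[ImageId, list[GroundTruthBox]] = {
            im.image_id: [] for im in self.images
        }
        for gt in self.ground_truth:
            out[gt.image_id].append(gt)
        return out


@dataclass
class DetectionSet:
    """All detections produced by one model over an image collection."""

    model_id: str
    detections: list[Detection]

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.model_id != self.model_id:
                raise ValidationError(
                    f"detection carries model_id {d.model_id!r}, "
                    f"set is {self.model_id!r}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def by_image(self) -> dict[ImageId, list[Detection]]:
        out: dict[ImageId, list[Detection]] = {}
        for d in self.detections:
            out.setdefault(d.image_id, []).append(d)
        return out


# ---------------------------------------------------------------------------
# COCO JSON interchange
# ---------------------------------------------------------------------------

def read_coco_ground_truth(path: str) -> Dataset:
    """Read a COCO annotation file into a :class:`Dataset`.

    Annotation ``bbox`` entries are ``[x, y, width, height]`` and are
    converted to corner form on read.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("images", "annotations", "categories"):
        if key not in raw:
            raise ParseError(f"{path}: missing COCO key {key!r}")
    images = [
        ImageInfo(im["id"], int(im["width"]), int(im["height"]))
        for im in raw["images"]
    ]
    categories = {int(c["id"]): str(c.get("name", c["id"])) for c in raw["categories"]}
    gts = []
    for ann in raw["annotations"]:
        x, y, w, h = ann["bbox"]
        gts.append(
            GroundTruthBox(
                image_id=ann["image_id"],
                box=Box.from_xywh(float(x), float(y), float(w), float(h)),
                category_id=int(ann["category_id"]),
            )
        )
    return Dataset(images=images, ground_truth=gts, categories=categories)


def write_coco_ground_truth(dataset: Dataset, path: str) -> None:
    raw = {
        "images": [
            {"id": im.image_id, "width": im.width, "height": im.height}
            for im in dataset.images
        ],
        "annotations": [
            {
                "id": i + 1,
                "image_id": gt.image_id,
                "category_id": gt.category_id,
                "bbox": list(gt.box.as_xywh()),
                "area": gt.box.area,
                "iscrowd": 0,
            }
            for i, gt in enumerate(dataset.ground_truth)
        ],
        "categories": [
            {"id": cid, "name": name} for cid, name in dataset.categories.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh)


def read_coco_detections(path: str, model_id: str) -> DetectionSet:
    """Read a COCO results file (list of result dicts) into a DetectionSet."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise ParseError(f"{path}: COCO results file must be a JSON list")
    dets = []
    for r in raw:
        x, y, w, h = r["bbox"]
        if w <= 0 or h <= 0:
            raise ValidationError(
                f"{path}: non-positive box size ({w}, {h}) "
                f"for image {r['image_id']!r}"
            )
        dets.append(
            Detection(
                image_id=r["image_id"],
                box=Box.from_xywh(float(x), float(y), float(w), float(h)),
                score=float(r["score"]),
                category_id=int(r["category_id"]),
                model_id=model_id,
            )
        )
    return DetectionSet(model_id=model_id, detections=dets)


def write_coco_detections(dets: DetectionSet, path: str) -> None:
    raw = [
        {
            "image_id": d.image_id,
            "category_id": d.category_id,
            "bbox": list(d.box.as_xywh()),
            "score": d.score,
        }
        for d in dets.detections
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "image_id",
    "model_id",
    "category_id",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "score",
)


def detections_to_csv(dets: DetectionSet, path: str) -> None:
    """Write one row per detection; header is mandatory, comma separated."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for d in dets.detections:
            writer.writerow(
                [
                    d.image_id,
                    d.model_id,
                    d.category_id,
                    repr(d.box.x_min),
                    repr(d.box.y_min),
                    repr(d.box.x_max),
                    repr(d.box.y_max),
                    repr(d.score),
                ]
            )


def csv_to_detections(path: str, image_id_type: type = int) -> DetectionSet:
    """Read a detection CSV written by :func:`detections_to_csv`.

    ``image_id_type`` converts the textual image id back to its native type
    (ids are commonly integers in COCO files).
    """
    dets: list[Detection] = []
    model_id = ""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != CSV_COLUMNS:
            raise ParseError(f"{path}: missing or unexpected CSV header")
        for row in reader:
            img, mid, cat, x0, y0, x1, y1, s = row
            model_id = mid
            dets.append(
                Detection(
                    image_id=image_id_type(img),
                    box=Box(float(x0), float(y0), float(x1), float(y1)),
                    score=float(s),
                    category_id=int(cat),
                    model_id=mid,
                )
            )
    return DetectionSet(model_id=model_id or "unknown", detections=dets)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _normalize_one(
    box: Box, width: int, height: int, clip: bool, image_id: ImageId
) -> Box:
    x0, y0, x1, y1 = box.x_min, box.y_min, box.x_max, box.y_max
    if clip and (x0 < 0 or y0 < 0 or x1 > width or y1 > height):
        logger.warning(
            "box (%.1f, %.1f, %.1f, %.1f) exceeds bounds of image %r "
            "(%dx%d); clipping",
            x0, y0, x1, y1, image_id, width, height,
        )
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(width)), min(y1, float(height))
    return Box(x0 / width, y0 / height, x1 / width, y1 / height, normalized=True)


def normalize_boxes(
    dets: DetectionSet, dataset: Dataset, clip: bool = True
) -> DetectionSet:
    """Scale all boxes to the unit square using per-image width/height.

    Boxes extending past the image border are clipped (with a logged warning)
    rather than rejected — detector outputs routinely overshoot borders.
    Set ``clip=False`` to keep overshooting coordinates (they then fail the
    normalized-range invariant and raise).
    """
    sizes = dataset.sizes()
    out = []
    for d in dets.detections:
        if d.box.normalized:
            out.append(d)
            continue
        w, h = sizes[d.image_id]
        out.append(replace(d, box=_normalize_one(d.box, w, h, clip, d.image_id)))
    return DetectionSet(model_id=dets.model_id, detections=out)


def denormalize_boxes(dets: DetectionSet, dataset: Dataset) -> DetectionSet:
    """Inverse of :func:`normalize_boxes` (exact up to rounding, <1e-9)."""
    sizes = dataset.sizes()
    out = []
    for d in dets.detections:
        if not d.box.normalized:
            out.append(d)
            continue
        w, h = sizes[d.image_id]
        b = d.box
        out.append(
            replace(
                d,
                box=Box(b.x_min * w, b.y_min * h, b.x_max * w, b.y_max * h,
                        normalized=False),
            )
        )
    return DetectionSet(model_id=dets.model_id, detections=out)


def concat_detection_sets(
    sets: Iterable[DetectionSet], model_id: str
) -> DetectionSet:
    """Pool several detection sets under a new model id."""
    dets = [replace(d, model_id=model_id) for s in sets for d in s.detections]
    return DetectionSet(model_id=model_id, detections=dets)
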