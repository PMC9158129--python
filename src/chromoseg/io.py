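"""Readers and writers for the formats the toolkit exchanges.

* COCO-style instance JSON — images/annotations/categories arrays with masks
  as *uncompressed, column-major* RLE (the COCO dialect: counts alternate
  background/foreground runs over the mask flattened in Fortran order,
  starting with background).  Detections travel in a ``detections`` array of
  the same file carrying raw and corrected confidences side by side; the
  corrected score never overwrites the raw one.
* 16-bit label PNGs — 0 is background, ``i`` is instance ``i``.  Overlapping
  instances cannot share one label map; they are written one PNG per
  instance, and single-map mode raises an explicit error on collision.
* CSV detection tables — one row per detection with box, confidences and
  corrected score, serialized at full double precision.

All round trips are lossless for binary masks and scores.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import Box, as_mask, mask_to_box
from .scoring import Detection

__all__ = [
    "DatasetBundle",
    "FormatError",
    "OverlapError",
    "rle_encode",
    "rle_decode",
    "write_coco_json",
    "read_coco_json",
    "write_label_png",
    "read_label_png",
    "write_instance_pngs",
    "read_instance_pngs",
    "write_detections_csv",
    "read_detections_csv",
    "write_image_png",
]


class FormatError(ValueError):
    """Malformed file content (bad RLE length, dangling references...)."""


class OverlapError(ValueError):
    """Overlapping instances offered to a single-label-map writer."""


@dataclass
class DatasetBundle:
    """In-memory dataset: images, ground truth and detections by image id."""

    image_sizes: dict[int, tuple[int, int]] = field(default_factory=dict)
    images: dict[int, np.ndarray] = field(default_factory=dict)
    gt_masks: dict[int, list[np.ndarray]] = field(default_factory=dict)
    detections: dict[int, list[Detection]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for img_id, masks in self.gt_masks.items():
            if img_id not in self.image_sizes:
                raise FormatError(f"gt references unknown image id {img_id}")
            for m in masks:
                if m.shape != self.image_sizes[img_id]:
                    raise FormatError(
                        f"mask shape {m.shape} does not match image "
                        f"{img_id} size {self.image_sizes[img_id]}"
                    )
        for img_id, dets in self.detections.items():
            if img_id not in self.image_sizes:
                raise FormatError(f"detection references unknown image id {img_id}")
            for d in dets:
                if d.mask.shape != self.image_sizes[img_id]:
                    raise FormatError(
                        f"detection mask shape {d.mask.shape} does not match "
                        f"image {img_id} size {self.image_sizes[img_id]}"
                    )


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed column-major RLE: ``{"size": [h, w], "counts": [...]}``."""
    mask = as_mask(mask)
    h, w = mask.shape
    flat = mask.ravel(order="F").astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    """Inverse of :func:`rle_encode`; validates the run-length sum."""
    h, w = rle["size"]
    counts = rle["counts"]
    if sum(counts) != h * w:
        raise FormatError(
            f"RLE counts sum to {sum(counts)}, expected {h * w} for size {h}x{w}"
        )
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def _box_to_xywh(b: Box) -> list[float]:
    return [b.x1, b.y1, b.x2 - b.x1, b.y2 - b.y1]


def _xywh_to_box(xywh: Sequence[float]) -> Box:
    x, y, w, h = xywh
    return Box(x, y, x + w, y + h)


def write_coco_json(bundle: DatasetBundle, path: str | Path) -> None:
    bundle.validate()
    images = [
        {"id": int(i), "height": int(hw[0]), "width": int(hw[1])}
        for i, hw in sorted(bundle.image_sizes.items())
    ]
    annotations = []
    ann_id = 1
    for img_id in sorted(bundle.gt_masks):
        for m in bundle.gt_masks[img_id]:
            m = as_mask(m)
            entry = {
                "id": ann_id,
                "image_id": int(img_id),
                "category_id": 1,
                "segmentation": rle_encode(m),
                "area": int(np.count_nonzero(m)),
                "iscrowd": 0,
            }
            if m.any():
                entry["bbox"] = _box_to_xywh(mask_to_box(m))
            annotations.append(entry)
            ann_id += 1
    detections = []
    for img_id in sorted(bundle.detections):
        for d in bundle.detections[img_id]:
            detections.append(
                {
                    "image_id": int(img_id),
                    "instance_id": int(d.instance_id),
                    "category_id": 1,
                    "segmentation": rle_encode(d.mask),
                    "bbox": _box_to_xywh(d.box),
                    "p_cls": float(d.p_cls),
                    "p_box": float(d.p_box),
                    "iou_mask": float(d.iou_mask_pred),
                    "score": None if d.score is None else float(d.score),
                }
            )
    doc = {
        "info": bundle.metadata,
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "chromosome"}],
        "detections": detections,
    }
    Path(path).write_text(json.dumps(doc))


def read_coco_json(path: str | Path) -> DatasetBundle:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed JSON in {path}: {e}") from e
    bundle = DatasetBundle(metadata=doc.get("info", {}))
    for img in doc.get("images", []):
        bundle.image_sizes[int(img["id"])] = (int(img["height"]), int(img["width"]))
    for ann in doc.get("annotations", []):
        img_id = int(ann["image_id"])
        if img_id not in bundle.image_sizes:
            raise FormatError(
                f"annotation {ann.get('id')} references unknown image id {img_id}"
            )
        seg = ann["segmentation"]
        if tuple(seg["size"]) != bundle.image_sizes[img_id]:
            raise FormatError(
                f"annotation {ann.get('id')}: RLE size {seg['size']} does not "
                f"match image {img_id}"
            )
        bundle.gt_masks.setdefault(img_id, []).append(rle_decode(seg))
    for det in doc.get("detections", []):
        img_id = int(det["image_id"])
        if img_id not in bundle.image_sizes:
            raise FormatError(
                f"detection references unknown image id {img_id}"
            )
        bundle.detections.setdefault(img_id, []).append(
            Detection(
                box=_xywh_to_box(det["bbox"]),
                mask=rle_decode(det["segmentation"]),
                p_cls=det["p_cls"],
                p_box=det["p_box"],
                iou_mask_pred=det["iou_mask"],
                instance_id=int(det["instance_id"]),
                image_id=img_id,
                score=det.get("score"),
            )
        )
    bundle.validate()
    return bundle


def write_label_png(masks: Sequence[np.ndarray], path: str | Path,
                    shape: tuple[int, int] | None = None) -> None:
    """All instances in one 16-bit label map; raises on overlap."""
    masks = [as_mask(m) for m in masks]
    if len(masks) > 65535:
        raise ValueError("a 16-bit label map holds at most 65535 instances")
    if masks:
        shape = masks[0].shape
    elif shape is None:
        raise ValueError("shape is required for an empty mask set")
    label = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        if (label[m] != 0).any():
            raise OverlapError(
                f"instance {i} overlaps an earlier instance; overlapping "
                "instances cannot share one label map — use "
                "write_instance_pngs (one PNG per instance) instead"
            )
        label[m] = i
    Image.fromarray(label).save(Path(path))


def read_label_png(path: str | Path) -> list[np.ndarray]:
    label = np.asarray(Image.open(Path(path)))
    return [label == i for i in range(1, int(label.max()) + 1)]


def write_instance_pngs(masks: Sequence[np.ndarray], directory: str | Path,
                        stem: str = "instance") -> list[Path]:
    """One binary 16-bit PNG per instance; supports overlapping masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(masks):
        p = directory / f"{stem}_{i:05d}.png"
        Image.fromarray(as_mask(m).astype(np.uint16)).save(p)
        paths.append(p)
    return paths


def read_instance_pngs(directory: str | Path, stem: str = "instance") -> list[np.ndarray]:
    paths = sorted(Path(directory).glob(f"{stem}_*.png"))
    return [np.asarray(Image.open(p)) > 0 for p in paths]


_CSV_FIELDS = [
    "image_id", "instance_id", "x1", "y1", "x2", "y2",
    "p_cls", "p_box", "iou_mask", "score",
]


def write_detections_csv(dets: Sequence[Detection], path: str | Path) -> None:
    """Detection table without masks (geometry + confidences only)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for d in dets:
            writer.writerow(
                [
                    d.image_id, d.instance_id,
                    repr(d.box.x1), repr(d.box.y1), repr(d.box.x2), repr(d.box.y2),
                    repr(d.p_cls), repr(d.p_box), repr(d.iou_mask_pred),
                    "" if d.score is None else repr(d.score),
                ]
            )


def read_detections_csv(path: str | Path, mask_shape: tuple[int, int] = (1, 1)
                        ) -> list[Detection]:
    """Read a detection table; masks are not stored in CSV and come back empty."""
    dets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_FIELDS:
            raise FormatError(
                f"unexpected CSV header {reader.fieldnames} in {path}"
            )
        for row in reader:
            dets.append(
                Detection(
                    box=Box(float(row["x1"]), float(row["y1"]),
                            float(row["x2"]), float(row["y2"])),
                    mask=np.zeros(mask_shape, dtype=bool),
                    p_cls=float(row["p_cls"]),
                    p_box=float(row["p_box"]),
                    iou_mask_pred=float(row["iou_mask"]),
                    instance_id=int(row["instance_id"]),
                    image_id=int(row["image_id"]),
                    score=float(row["score"]) if row["score"] else None,
                )
            )
    return dets


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Grayscale image in [0, 1] as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(Path(path))
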