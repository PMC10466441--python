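"""Inference: letterbox preprocessing, the forward pass, decoding, NMS and
coordinate back-mapping to the original image frame.

Letterboxing resizes with preserved aspect ratio to the square network input
(default 416) and pads with mid-gray; the transform is recorded so detected
boxes can be mapped back to original-image pixels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import csv
import numpy as np
from PIL import Image

from .boxes import BoundingBox, MICRONS_PER_PIXEL, calibrate_length, iou, nms
from .net.yolov3 import YoloV3, decode_boxes

__all__ = [
    "DetectionSet",
    "LetterboxTransform",
    "letterbox_image",
    "load_image",
    "run_inference",
    "write_detections_csv",
    "read_detections_csv",
    "iou",
    "nms",
    "calibrate_length",
]


@dataclass(frozen=True)
class LetterboxTransform:
    """Forward/backward mapping between original and letterboxed coordinates."""

    scale: float
    pad_x: float
    pad_y: float
    orig_width: int
    orig_height: int

    def to_network(self, box: BoundingBox) -> BoundingBox:
        return replace(
            box,
            xmin=box.xmin * self.scale + self.pad_x,
            ymin=box.ymin * self.scale + self.pad_y,
            xmax=box.xmax * self.scale + self.pad_x,
            ymax=box.ymax * self.scale + self.pad_y,
        )

    def to_original(self, box: BoundingBox) -> BoundingBox:
        b = replace(
            box,
            xmin=(box.xmin - self.pad_x) / self.scale,
            ymin=(box.ymin - self.pad_y) / self.scale,
            xmax=(box.xmax - self.pad_x) / self.scale,
            ymax=(box.ymax - self.pad_y) / self.scale,
        )
        return b.clipped(self.orig_width, self.orig_height)


@dataclass
class DetectionSet:
    """All post-NMS detections of one image, with physical calibration."""

    image_id: str
    boxes: list[BoundingBox] = field(default_factory=list)
    um_per_pixel: float = MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as 8-bit grayscale (H, W) array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc


def letterbox_image(
    image: np.ndarray, input_size: int = 416
) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize + mid-gray pad to ``input_size`` square.

    Returns the network input as (3, S, S) float32 in [0, 1] (grayscale
    replicated to three channels) and the coordinate transform.
    """
    h, w = image.shape[:2]
    scale = input_size / max(h, w)
    nw, nh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = np.asarray(
        Image.fromarray(image.astype(np.uint8), mode="L").resize((nw, nh), Image.BILINEAR)
    )
    canvas = np.full((input_size, input_size), 128, dtype=np.uint8)
    pad_x, pad_y = (input_size - nw) // 2, (input_size - nh) // 2
    canvas[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    x = (canvas.astype(np.float32) / 255.0)[None].repeat(3, axis=0)
    return x, LetterboxTransform(scale, float(pad_x), float(pad_y), w, h)


def run_inference(
    detector: YoloV3,
    image: np.ndarray | str | Path,
    confidence_threshold: float = 0.5,
    nms_iou_threshold: float = 0.45,
    um_per_pixel: float = MICRONS_PER_PIXEL,
    class_names: Sequence[str] | None = None,
    image_id: str | None = None,
) -> DetectionSet:
    """Detect organoids in one image.

    Pipeline: letterbox -> forward (inference batch-norm statistics) ->
    decode -> confidence filter -> per-class NMS -> map back to original
    pixels -> clip. ``class_names`` defaults to ["organoid"] for one-class
    models and ["active", "aging"] for two-class models.
    """
    if isinstance(image, (str, Path)):
        image_id = image_id or Path(image).stem
        image = load_image(image)
    image_id = image_id or "image"
    if class_names is None:
        class_names = ["organoid"] if detector.num_classes == 1 else ["active", "aging"]
    x, tf = letterbox_image(image, detector.input_size)
    raws = detector.forward(x[None], train=False)
    boxes = decode_boxes(
        [r[0] for r in raws], detector.anchors, detector.input_size,
        confidence_threshold=confidence_threshold, class_names=class_names,
    )
    kept = nms(boxes, nms_iou_threshold)
    mapped = [tf.to_original(b) for b in kept]
    return DetectionSet(image_id=image_id, boxes=mapped, um_per_pixel=um_per_pixel)


DETECTIONS_HEADER = ["image_id", "label", "confidence", "xmin", "ymin", "xmax", "ymax"]


def write_detections_csv(detection_sets: Sequence[DetectionSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTIONS_HEADER + ["um_per_pixel"])
        for ds in detection_sets:
            for b in ds.boxes:
                writer.writerow(
                    [ds.image_id, b.label, b.confidence, b.xmin, b.ymin, b.xmax, b.ymax, ds.um_per_pixel]
                )


def read_detections_csv(path: str | Path) -> list[DetectionSet]:
    by_image: dict[str, DetectionSet] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ds = by_image.setdefault(
                row["image_id"],
                DetectionSet(row["image_id"], [], float(row.get("um_per_pixel", MICRONS_PER_PIXEL))),
            )
            ds.boxes.append(
                BoundingBox(
                    float(row["xmin"]), float(row["ymin"]), float(row["xmax"]), float(row["ymax"]),
                    label=row["label"],
                    confidence=float(row["confidence"]) if row["confidence"] else None,
                )
            )
    return list(by_image.values())
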