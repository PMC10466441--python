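"""Axis-aligned bounding boxes and the overlap/suppression primitives built on them.

Coordinates follow the package-wide internal convention: 0-based, half-open
``[xmin, xmax) x [ymin, ymax)`` in pixels, so ``width = xmax - xmin`` with no
off-by-one arithmetic. Conversion to the 1-based inclusive Pascal-VOC file
convention happens only in :mod:`orgadetect.voc_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = ["BoundingBox", "iou", "nms", "calibrate_length", "MICRONS_PER_PIXEL"]

#: Physical calibration of the source microscope: one pixel edge is 0.833 um
#: at 100x magnification.
MICRONS_PER_PIXEL = 0.833


@dataclass(frozen=True)
class BoundingBox:
    """A labelled axis-aligned rectangle, the atom of annotation and detection.

    ``confidence`` is present on detections (in ``(0, 1]``) and ``None`` on
    ground-truth boxes.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "organoid"
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.confidence is not None and not (0.0 < self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside (0, 1]")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def clipped(self, width: float, height: float) -> "BoundingBox":
        """Clip to a ``width x height`` canvas, keeping at least a sliver."""
        return replace(
            self,
            xmin=min(max(self.xmin, 0.0), width - 1e-6),
            ymin=min(max(self.ymin, 0.0), height - 1e-6),
            xmax=max(min(self.xmax, width), 1e-6),
            ymax=max(min(self.ymax, height), 1e-6),
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in ``[0, 1]``."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(boxes: Sequence[BoundingBox], iou_threshold: float = 0.45) -> list[BoundingBox]:
    """Greedy per-class non-maximum suppression.

    Repeatedly keeps the highest-confidence box and discards same-class boxes
    overlapping it with IoU strictly above ``iou_threshold``. Output is sorted
    by confidence descending; ties broken by input order (stable).
    """
    for b in boxes:
        if b.confidence is None:
            raise ValueError("nms requires confidences on every box")
    order = sorted(range(len(boxes)), key=lambda i: -boxes[i].confidence)
    keep: list[BoundingBox] = []
    suppressed = [False] * len(boxes)
    for rank, i in enumerate(order):
        if suppressed[i]:
            continue
        keep.append(boxes[i])
        for j in order[rank + 1 :]:
            if (
                not suppressed[j]
                and boxes[j].label == boxes[i].label
                and iou(boxes[i], boxes[j]) > iou_threshold
            ):
                suppressed[j] = True
    return keep


def calibrate_length(length_px: float, um_per_pixel: float = MICRONS_PER_PIXEL) -> float:
    """Convert a pixel length to microns (default 0.833 um per pixel)."""
    if length_px < 0:
        raise ValueError(f"negative length: {length_px}")
    if um_per_pixel <= 0:
        raise ValueError(f"non-positive calibration: {um_per_pixel}")
    return length_px * um_per_pixel
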