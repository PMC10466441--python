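"""Pascal-VOC XML annotation I/O and deterministic dataset splitting.

VOC files (as written by LabelImg) store boxes 1-based and inclusive:
``xmin=1, xmax=10`` spans pixels 1..10, i.e. 10 pixels. Internally the package
uses 0-based half-open boxes, so on read ``xmin_internal = xmin_voc - 1`` and
``xmax_internal = xmax_voc``; writing applies the inverse. The conversion is
confined to this module.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from lxml import etree

from .boxes import BoundingBox

__all__ = ["Annotation", "DatasetSplit", "read_voc", "write_voc", "split_dataset"]


@dataclass
class Annotation:
    """All ground-truth boxes of one image, with the image geometry."""

    image_path: str
    image_width: int
    image_height: int
    boxes: list[BoundingBox] = field(default_factory=list)

    def validate(self) -> None:
        for i, b in enumerate(self.boxes):
            if not (0 <= b.xmin < b.xmax <= self.image_width):
                raise ValueError(f"object {i}: x-extent {b.xmin}..{b.xmax} outside image")
            if not (0 <= b.ymin < b.ymax <= self.image_height):
                raise ValueError(f"object {i}: y-extent {b.ymin}..{b.ymax} outside image")


@dataclass(frozen=True)
class DatasetSplit:
    """A disjoint train/test partition produced by a seeded shuffle."""

    train: list
    test: list
    ratio: tuple[int, int]
    seed: int


def read_voc(xml_path: str | Path) -> Annotation:
    """Parse one VOC XML file into an :class:`Annotation`.

    Raises a parse error naming the file for malformed XML and a validation
    error naming the object index for a box with non-positive extent.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML at {xml_path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{xml_path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    filename = root.findtext("filename") or xml_path.with_suffix(".png").name
    folder = root.findtext("folder") or ""
    image_path = str(Path(folder) / filename) if folder else filename

    boxes: list[BoundingBox] = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        xmin = float(bnd.findtext("xmin")) - 1.0
        ymin = float(bnd.findtext("ymin")) - 1.0
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"{xml_path}: object {i} has non-positive extent")
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, label=name))
    ann = Annotation(image_path, width, height, boxes)
    ann.validate()
    return ann


def write_voc(annotation: Annotation, xml_path: str | Path) -> None:
    """Write an :class:`Annotation` as LabelImg-dialect VOC XML (round-trips with
    :func:`read_voc`)."""
    annotation.validate()
    p = Path(annotation.image_path)
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = str(p.parent) if str(p.parent) != "." else ""
    etree.SubElement(root, "filename").text = p.name
    etree.SubElement(root, "path").text = str(p)
    src = etree.SubElement(root, "source")
    etree.SubElement(src, "database").text = "Unknown"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(annotation.image_width)
    etree.SubElement(size, "height").text = str(annotation.image_height)
    etree.SubElement(size, "depth").text = "1"
    etree.SubElement(root, "segmented").text = "0"
    for b in annotation.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(b.xmin)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(b.ymin)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(b.xmax)))
        etree.SubElement(bnd, "ymax").text = str(int(round(b.ymax)))
    tree = etree.ElementTree(root)
    tree.write(str(xml_path), pretty_print=True, encoding="utf-8")


def split_dataset(
    items: Sequence, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> DatasetSplit:
    """Deterministic seeded shuffle followed by a ``ratio`` partition.

    With 2,000 items at 4:1 this yields exactly 1,600 train / 400 test. The
    split is at the image level so no image's organoids leak across partitions.
    """
    if len(items) == 0:
        raise ValueError("cannot split an empty item list")
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio}")
    order = list(items)
    random.Random(seed).shuffle(order)
    n_train = int(round(len(order) * ratio[0] / (ratio[0] + ratio[1])))
    n_train = min(max(n_train, 1), len(order) - 1) if len(order) > 1 else n_train
    return DatasetSplit(order[:n_train], order[n_train:], tuple(ratio), seed)
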