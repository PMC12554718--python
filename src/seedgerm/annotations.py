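"""Annotation file formats.

Ground truth comes as Pascal VOC XML (the LabelImg dialect, one file per
image, classes "yes" = germinated / "no" = ungerminated) or YOLO text
(one ``class x_center y_center w h`` line per box, coordinates normalized
by image size). Predictions are read from JSON lines, one object per line:

    {"image": "dish_0001", "label": "yes",
     "box": [x_min, y_min, x_max, y_max], "confidence": 0.93}

All pixel coordinates in memory are 0-based and half-open, [min, max).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

from .metrics import DetectionBox

#: fixed class order used for YOLO integer class indices
YOLO_CLASSES = ("yes", "no")


def write_voc_xml(
    path: str | Path,
    image_name: str,
    image_size: tuple[int, int],
    boxes: Sequence[DetectionBox],
) -> None:
    """Write boxes as a Pascal VOC XML file. ``image_size`` is (H, W)."""
    height, width = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for box in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(box.x_min)
        ET.SubElement(bnd, "ymin").text = _fmt(box.y_min)
        ET.SubElement(bnd, "xmax").text = _fmt(box.x_max)
        ET.SubElement(bnd, "ymax").text = _fmt(box.y_max)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_voc_xml(path: str | Path) -> tuple[str, tuple[int, int], list[DetectionBox]]:
    """Read a VOC XML file -> (image name, (H, W), ground-truth boxes)."""
    root = ET.parse(path).getroot()
    name = root.findtext("filename", default=Path(path).stem)
    width = int(root.findtext("size/width", default="0"))
    height = int(root.findtext("size/height", default="0"))
    boxes = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        boxes.append(
            DetectionBox(
                x_min=float(bnd.findtext("xmin")),
                y_min=float(bnd.findtext("ymin")),
                x_max=float(bnd.findtext("xmax")),
                y_max=float(bnd.findtext("ymax")),
                label=obj.findtext("name"),
                confidence=1.0,
            )
        )
    return name, (height, width), boxes


def write_yolo_txt(
    path: str | Path,
    image_size: tuple[int, int],
    boxes: Sequence[DetectionBox],
    classes: Sequence[str] = YOLO_CLASSES,
) -> None:
    """Write boxes as YOLO-normalized ``class xc yc w h`` lines."""
    height, width = image_size
    lines = []
    for box in boxes:
        cls = classes.index(box.label)
        xc = (box.x_min + box.x_max) / 2 / width
        yc = (box.y_min + box.y_max) / 2 / height
        w = (box.x_max - box.x_min) / width
        h = (box.y_max - box.y_min) / height
        lines.append(f"{cls} {xc:.6f} {yc:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(
    path: str | Path,
    image_size: tuple[int, int],
    classes: Sequence[str] = YOLO_CLASSES,
) -> list[DetectionBox]:
    """Read YOLO lines back into pixel-coordinate boxes."""
    height, width = image_size
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        cls, xc, yc, w, h = int(parts[0]), *map(float, parts[1:5])
        boxes.append(
            DetectionBox(
                x_min=(xc - w / 2) * width,
                y_min=(yc - h / 2) * height,
                x_max=(xc + w / 2) * width,
                y_max=(yc + h / 2) * height,
                label=classes[cls],
                confidence=1.0,
            )
        )
    return boxes


def read_truth_dir(
    path: str | Path,
    image_size: tuple[int, int] | None = None,
) -> dict[str, list[DetectionBox]]:
    """Read every VOC .xml (and YOLO .txt, if a size is given) in a directory.

    Returns a mapping image-stem -> ground-truth boxes.
    """
    path = Path(path)
    truths: dict[str, list[DetectionBox]] = {}
    for xml in sorted(path.glob("*.xml")):
        _, _, boxes = read_voc_xml(xml)
        truths[xml.stem] = boxes
    for txt in sorted(path.glob("*.txt")):
        if image_size is None:
            raise ValueError("YOLO annotations need an image size")
        truths[txt.stem] = read_yolo_txt(txt, image_size)
    if not truths:
        raise ValueError(f"no annotation files found in {path}")
    return truths


def write_predictions_jsonl(
    path: str | Path, preds_by_image: Mapping[str, Iterable[DetectionBox]]
) -> None:
    with open(path, "w") as fh:
        for image in sorted(preds_by_image):
            for box in preds_by_image[image]:
                fh.write(
                    json.dumps(
                        {
                            "image": image,
                            "label": box.label,
                            "box": [box.x_min, box.y_min, box.x_max, box.y_max],
                            "confidence": box.confidence,
                        }
                    )
                    + "\n"
                )


def read_predictions_jsonl(path: str | Path) -> dict[str, list[DetectionBox]]:
    preds: dict[str, list[DetectionBox]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        box = rec["box"]
        preds.setdefault(rec["image"], []).append(
            DetectionBox(
                x_min=box[0], y_min=box[1], x_max=box[2], y_max=box[3],
                label=rec["label"], confidence=rec.get("confidence", 1.0),
            )
        )
    return preds


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))
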