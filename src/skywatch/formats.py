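"""Annotation and detection file formats.

Internally everything is 0-based, half-open pixel boxes; conversions happen
only here, at the format boundary:

* **darknet txt** — one file per frame, one object per line:
  ``class_id cx cy w h`` with all four geometry fields as fractions of the
  frame dimensions (the YOLO export dialect of the usual annotation tools).
* **Pascal-VOC XML** — ``xmin/ymin/xmax/ymax`` are 1-based and inclusive, so
  a VOC box (1, 1, 10, 10) is the internal box (0, 0, 10, 10).
* **detections** — line-delimited JSON with a schema-version header record;
  lossless round trip (floats survive via JSON's repr round-tripping).
"""

from __future__ import annotations

import json
import os
import re

from lxml import etree

from .geometry import BBox, Detection, GroundTruthBox

DETECTIONS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# darknet txt


def read_darknet_annotations(
    path: str, frame_w: int, frame_h: int, frame_index: int = 0
) -> list[GroundTruthBox]:
    """Read one frame's darknet-txt annotations into absolute-pixel boxes."""
    gts: list[GroundTruthBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 'class cx cy w h', got {line!r}"
                )
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number in {line!r}") from exc
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"{path}:{lineno}: {name}={v} outside [0, 1]"
                    )
            box = BBox(
                x=(cx - w / 2.0) * frame_w,
                y=(cy - h / 2.0) * frame_h,
                w=w * frame_w,
                h=h * frame_h,
            )
            gts.append(GroundTruthBox(box, frame_index=frame_index, label=f"class{cls}" if cls else "bird"))
    return gts


def write_darknet_annotations(
    path: str, gts: list[GroundTruthBox], frame_w: int, frame_h: int
) -> None:
    """Write one frame's boxes in darknet-txt normalised centre format."""
    with open(path, "w") as fh:
        for g in gts:
            b = g.box
            fh.write(
                f"0 {b.cx / frame_w:.6f} {b.cy / frame_h:.6f} "
                f"{b.w / frame_w:.6f} {b.h / frame_h:.6f}\n"
            )


_FRAME_RE = re.compile(r"(\d+)")


def frame_index_from_name(name: str) -> int:
    """Frame index from a file name: the last run of digits in the stem."""
    stem = os.path.splitext(os.path.basename(name))[0]
    matches = _FRAME_RE.findall(stem)
    if not matches:
        raise ValueError(f"no frame index found in file name {name!r}")
    return int(matches[-1])


def read_darknet_annotation_dir(
    dirpath: str, frame_w: int, frame_h: int
) -> list[GroundTruthBox]:
    """Read every ``*.txt`` in a directory, taking frame indices from names."""
    gts: list[GroundTruthBox] = []
    for name in sorted(os.listdir(dirpath)):
        if not name.endswith(".txt"):
            continue
        idx = frame_index_from_name(name)
        gts.extend(
            read_darknet_annotations(os.path.join(dirpath, name), frame_w, frame_h, idx)
        )
    return gts


# ---------------------------------------------------------------------------
# Pascal-VOC XML


def _voc_int(obj, elem: str, path: str):
    node = obj.find(elem)
    if node is None or node.text is None:
        raise ValueError(f"{path}: missing element {elem!r} under <{obj.tag}>")
    return int(round(float(node.text)))


def read_voc_xml(path: str, frame_index: int = 0) -> list[GroundTruthBox]:
    """Read a Pascal-VOC XML annotation file.

    VOC stores 1-based inclusive corners; ``xmin=1, xmax=10`` spans pixels
    1..10 inclusive, i.e. the internal half-open box x=0, w=10.  A ``<size>``
    element is required so the annotation is self-describing.
    """
    tree = etree.parse(path)
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing required <size> element")
    _voc_int(size, "width", path)
    _voc_int(size, "height", path)
    gts: list[GroundTruthBox] = []
    for obj in root.iter("object"):
        name_node = obj.find("name")
        label = name_node.text if name_node is not None and name_node.text else "bird"
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: <object> without <bndbox>")
        xmin = _voc_int(bnd, "xmin", path)
        ymin = _voc_int(bnd, "ymin", path)
        xmax = _voc_int(bnd, "xmax", path)
        ymax = _voc_int(bnd, "ymax", path)
        box = BBox(x=xmin - 1, y=ymin - 1, w=xmax - xmin + 1, h=ymax - ymin + 1)
        gts.append(GroundTruthBox(box, frame_index=frame_index, label=label))
    return gts


# ---------------------------------------------------------------------------
# detections


def write_detections(path: str, dets: list[Detection]) -> None:
    """Line-delimited JSON, schema-versioned, lossless."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema_version": DETECTIONS_SCHEMA_VERSION}) + "\n")
        for d in dets:
            fh.write(
                json.dumps(
                    {
                        "frame": d.frame_index,
                        "x": d.box.x,
                        "y": d.box.y,
                        "w": d.box.w,
                        "h": d.box.h,
                        "confidence": d.confidence,
                        "source_id": d.source_id,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_detections(path: str) -> list[Detection]:
    dets: list[Detection] = []
    with open(path) as fh:
        header = json.loads(fh.readline())
        version = header.get("schema_version")
        if version != DETECTIONS_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported detections schema version {version!r}"
            )
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            dets.append(
                Detection(
                    BBox(rec["x"], rec["y"], rec["w"], rec["h"]),
                    rec["confidence"],
                    rec["frame"],
                    rec.get("source_id", ""),
                )
            )
    return dets
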