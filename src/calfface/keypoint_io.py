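"""Readers and writers for standard pose-annotation dialects.

Two dialects are supported:

* **COCO keypoints JSON** — ``images`` / ``annotations`` / ``categories``
  arrays, each annotation carrying a flat ``[x1, y1, v1, x2, y2, v2, ...]``
  triplet list in pixel units.
* **YOLO pose text** — one detection per line:
  ``class cx cy w h  x1 y1 c1  x2 y2 c2 ...`` with every value normalized
  to ``[0, 1]`` by the image width/height.

Everything downstream of this module works in pixels; normalized
coordinates never escape the YOLO reader.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Sequence

from .schema import KeypointFrame, KeypointSchema, SchemaError

__all__ = [
    "read_coco_keypoints",
    "write_coco_keypoints",
    "read_yolo_pose",
    "write_yolo_pose",
    "write_phenotype_table",
    "read_phenotype_table",
    "KeypointIOError",
]

#: Default confidence threshold above which a YOLO keypoint is visible.
DEFAULT_VISIBILITY_THRESHOLD = 0.5


class KeypointIOError(ValueError):
    """A pose file could not be parsed."""


def _triplets_to_frame(
    triplets: Sequence[float],
    schema: KeypointSchema,
    frame_index: int,
    image_size: tuple[int, int],
    bbox,
    source: str,
) -> KeypointFrame:
    n = len(schema)
    if len(triplets) != 3 * n:
        raise SchemaError(
            f"{source}: expected {3 * n} keypoint values for {n} keypoints, "
            f"found {len(triplets)}"
        )
    points: dict[str, tuple[float, float]] = {}
    visibility: dict[str, int] = {}
    for i, label in enumerate(schema):
        x, y, v = triplets[3 * i : 3 * i + 3]
        visibility[label] = int(v)
        points[label] = (float(x), float(y))
    return KeypointFrame(
        frame_index=frame_index,
        points=points,
        visibility=visibility,
        image_size=image_size,
        bbox=tuple(bbox) if bbox is not None else None,
    )


def read_coco_keypoints(
    path: str | Path, schema: KeypointSchema
) -> list[tuple[int, KeypointFrame]]:
    """Read a COCO keypoints JSON file.

    Returns ``(image_id, frame)`` pairs ordered by image id; the image id
    doubles as the frame index.  Occluded keypoints (v=1) are kept and
    flagged by their visibility value; absent keypoints (v=0) carry
    meaningless coordinates which downstream code must ignore.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise KeypointIOError(f"malformed COCO JSON in {path}: {exc}") from exc
    try:
        images = {img["id"]: img for img in doc["images"]}
        annotations = doc["annotations"]
    except (KeyError, TypeError) as exc:
        raise KeypointIOError(f"{path} is not COCO keypoints JSON: missing {exc}") from exc

    out: list[tuple[int, KeypointFrame]] = []
    for ann in sorted(annotations, key=lambda a: a["image_id"]):
        img = images[ann["image_id"]]
        frame = _triplets_to_frame(
            ann["keypoints"],
            schema,
            frame_index=int(ann["image_id"]),
            image_size=(int(img["width"]), int(img["height"])),
            bbox=ann.get("bbox"),
            source=f"{path} annotation {ann.get('id')}",
        )
        out.append((int(ann["image_id"]), frame))
    return out


def write_coco_keypoints(
    frames: Sequence[KeypointFrame],
    path: str | Path,
    schema: KeypointSchema,
    category_name: str = "calf_face",
) -> None:
    """Write frames as a single-category COCO keypoints JSON file."""
    images, annotations = [], []
    for i, frame in enumerate(frames):
        w, h = frame.image_size
        images.append(
            {"id": frame.frame_index, "width": w, "height": h,
             "file_name": f"frame_{frame.frame_index:06d}.jpg"}
        )
        triplets: list[float] = []
        for label in schema:
            x, y = frame.points[label]
            v = frame.visibility[label]
            triplets.extend([round(x, 6), round(y, 6), v])
        ann = {
            "id": i,
            "image_id": frame.frame_index,
            "category_id": 1,
            "keypoints": triplets,
            "num_keypoints": sum(1 for l in schema if frame.visibility[l] > 0),
        }
        if frame.bbox is not None:
            ann["bbox"] = [round(v, 6) for v in frame.bbox]
            ann["area"] = round(frame.bbox[2] * frame.bbox[3], 6)
        annotations.append(ann)
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {
                "id": 1,
                "name": category_name,
                "keypoints": list(schema.names),
                "skeleton": [
                    [schema.index(a) + 1, schema.index(b) + 1]
                    for a, b in schema.skeleton
                ],
            }
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_yolo_pose(
    path: str | Path,
    image_size: tuple[int, int],
    schema: KeypointSchema,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    frame_index: int = 0,
) -> KeypointFrame:
    """Read one YOLO pose text file (one frame, one animal).

    Coordinates are denormalized to pixels.  A keypoint's confidence is
    mapped to visibility 2 when ``conf >= visibility_threshold`` and 0
    otherwise.  If the file holds several detection lines the
    highest-confidence one is used and a warning is emitted — source videos
    are split to one calf each, so multiple detections indicate an upstream
    problem.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise KeypointIOError(f"{path}: no detection lines")

    n = len(schema)
    expected = 5 + 3 * n
    parsed = []
    for ln in lines:
        tokens = ln.split()
        if len(tokens) != expected:
            raise KeypointIOError(
                f"{path}: expected {expected} tokens "
                f"(class + bbox + {n} keypoints x 3), found {len(tokens)}"
            )
        vals = [float(t) for t in tokens[1:]]
        conf_sum = sum(vals[4 + 3 * i + 2] for i in range(n))
        parsed.append((conf_sum, vals))
    if len(parsed) > 1:
        warnings.warn(
            f"{path}: {len(parsed)} detections in a single-animal file; "
            "keeping the highest-confidence one",
            stacklevel=2,
        )
    vals = max(parsed, key=lambda p: p[0])[1]

    w, h = image_size
    cx, cy, bw, bh = vals[:4]
    bbox = ((cx - bw / 2) * w, (cy - bh / 2) * h, bw * w, bh * h)
    points, visibility = {}, {}
    for i, label in enumerate(schema):
        x, y, conf = vals[4 + 3 * i : 4 + 3 * i + 3]
        points[label] = (x * w, y * h)
        visibility[label] = 2 if conf >= visibility_threshold else 0
    return KeypointFrame(
        frame_index=frame_index,
        points=points,
        visibility=visibility,
        image_size=image_size,
        bbox=bbox,
    )


def write_yolo_pose(
    frame: KeypointFrame, path: str | Path, schema: KeypointSchema, class_id: int = 0
) -> None:
    """Write a frame as one YOLO pose text line, normalized by image size."""
    w, h = frame.image_size
    if frame.bbox is not None:
        bx, by, bw, bh = frame.bbox
    else:
        xs = [frame.points[l][0] for l in schema if frame.visibility[l] > 0]
        ys = [frame.points[l][1] for l in schema if frame.visibility[l] > 0]
        bx, by = min(xs), min(ys)
        bw, bh = max(xs) - bx, max(ys) - by
    tokens = [
        str(class_id),
        f"{(bx + bw / 2) / w:.6f}",
        f"{(by + bh / 2) / h:.6f}",
        f"{bw / w:.6f}",
        f"{bh / h:.6f}",
    ]
    for label in schema:
        x, y = frame.points[label]
        conf = 1.0 if frame.visibility[label] > 0 else 0.0
        tokens += [f"{x / w:.6f}", f"{y / h:.6f}", f"{conf:.6f}"]
    Path(path).write_text(" ".join(tokens) + "\n")


def write_phenotype_table(records: Sequence[dict], path: str | Path) -> None:
    """Write per-session phenotype records as a UTF-8 CSV with header.

    ``records`` are flat mappings sharing one column set; units are encoded
    in the column names (``_cm``, ``_s``, ``_count``).  An empty record list
    produces a header-only file with the canonical columns.
    """
    from .pipeline import PHENOTYPE_COLUMNS

    path = Path(path)
    if records:
        columns = list(records[0].keys())
        for rec in records[1:]:
            if list(rec.keys()) != columns:
                raise ValueError("phenotype records do not share one column schema")
    else:
        columns = list(PHENOTYPE_COLUMNS)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        writer.writerows(records)


def read_phenotype_table(path: str | Path):
    """Read a phenotype CSV back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)
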