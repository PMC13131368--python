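"""Core data types: keypoint schema, per-frame keypoints, trajectories.

All geometry downstream of I/O operates in *pixel* coordinates with the
image convention: origin at the top-left corner, x increasing rightward,
y increasing downward, continuous (sub-pixel) values allowed.

Visibility follows the COCO convention:

* 0 — keypoint absent / not labeled (coordinates are meaningless),
* 1 — labeled but occluded,
* 2 — labeled and visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "KeypointSchema",
    "KeypointFrame",
    "Trajectory",
    "CALF_FACE_10",
    "SchemaError",
]

Point = tuple[float, float]


class SchemaError(ValueError):
    """A keypoint record does not conform to its declared schema."""


@dataclass(frozen=True)
class KeypointSchema:
    """An ordered, unique set of keypoint labels with an optional skeleton.

    The skeleton is a list of label pairs used only for visualization; it
    plays no role in any computation.
    """

    names: tuple[str, ...]
    skeleton: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError(f"duplicate keypoint labels in schema: {self.names}")
        for a, b in self.skeleton:
            if a not in self.names or b not in self.names:
                raise SchemaError(f"skeleton edge ({a}, {b}) uses unknown label")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)


#: The canonical 10-landmark calf-face schema: ear tips and attachment
#: points, upper/lower eyelid landmarks, and the two nostrils.  This is the
#: minimal landmark set supporting ear angulation, eye opening and nostril
#: distance.
CALF_FACE_10 = KeypointSchema(
    names=(
        "left_ear_tip",
        "left_ear_base",
        "right_ear_tip",
        "right_ear_base",
        "left_eye_top",
        "left_eye_bottom",
        "right_eye_top",
        "right_eye_bottom",
        "left_nostril",
        "right_nostril",
    ),
    skeleton=(
        ("left_ear_tip", "left_ear_base"),
        ("right_ear_tip", "right_ear_base"),
        ("left_eye_top", "left_eye_bottom"),
        ("right_eye_top", "right_eye_bottom"),
        ("left_nostril", "right_nostril"),
    ),
)


@dataclass
class KeypointFrame:
    """Named 2D keypoints for one animal in one frame.

    Coordinates are pixels.  ``bbox`` is ``(x, y, width, height)`` of the
    head bounding box when known; ``image_size`` is ``(width, height)``.
    """

    frame_index: int
    points: dict[str, Point]
    visibility: dict[str, int]
    image_size: tuple[int, int]
    bbox: Optional[tuple[float, float, float, float]] = None

    def validate(self, schema: KeypointSchema) -> None:
        """Raise :class:`SchemaError` if the frame violates the schema."""
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        for label in schema:
            if label not in self.points or label not in self.visibility:
                raise SchemaError(f"frame {self.frame_index}: missing label {label!r}")
        w, h = self.image_size
        for label in schema:
            v = self.visibility[label]
            if v not in (0, 1, 2):
                raise SchemaError(
                    f"frame {self.frame_index}: visibility of {label!r} is {v}, "
                    "expected 0, 1 or 2"
                )
            if v > 0:
                x, y = self.points[label]
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise SchemaError(
                        f"frame {self.frame_index}: non-finite coordinates for {label!r}"
                    )
                if not (0 <= x <= w and 0 <= y <= h):
                    raise SchemaError(
                        f"frame {self.frame_index}: {label!r} at ({x:.1f}, {y:.1f}) "
                        f"outside image {w}x{h}"
                    )

    def is_visible(self, label: str) -> bool:
        """True when the keypoint is labeled (occluded counts as labeled)."""
        return self.visibility.get(label, 0) > 0


@dataclass
class Trajectory:
    """Time-ordered frames for one animal in one recording session."""

    animal_id: str
    session_id: str
    frames: list[KeypointFrame] = field(default_factory=list)
    frame_rate: float = 1.0  # frames per second; videos are sampled at 1 fps

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[KeypointFrame]:
        return iter(self.frames)

    def validate(self, schema: KeypointSchema) -> None:
        for frame in self.frames:
            frame.validate(schema)


def as_point_array(frame: KeypointFrame, schema: KeypointSchema):
    """Return (coords ndarray (n, 2), visibility ndarray (n,)) in schema order."""
    import numpy as np

    xy = np.array([frame.points[name] for name in schema], dtype=float)
    vis = np.array([frame.visibility[name] for name in schema], dtype=int)
    return xy, vis
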