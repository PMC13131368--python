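"""Per-frame geometric trait extraction.

Ear posture is measured as the angle at the ear attachment point (the
hinge of ear rotation) in the triangle formed with the ear tip and the
upper-eyelid landmark of the same side, computed with the law of cosines:

    cos(theta) = (a^2 + c^2 - b^2) / (2 a c)

with a = |base - tip|, c = |base - eye_top|, b = |tip - eye_top|.  An
angle above 90 degrees is a *backward* ear, at or below 90 degrees a
*frontward* ear.

Eye opening and nostril distance are plain Euclidean distances converted
from pixels to centimeters with a fiducial calibration: the animal's ear
tag has a known physical size, so its pixel extent fixes cm-per-pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from .schema import CALF_FACE_10, KeypointFrame, KeypointSchema

__all__ = [
    "EarAngleResult",
    "ScaleCalibration",
    "FramePhenotypes",
    "euclidean_distance",
    "ear_angle",
    "classify_ear_position",
    "paired_distance_cm",
    "extract_frame_phenotypes",
    "DegenerateGeometryError",
]

Point = tuple[float, float]
Position = Literal["frontward", "backward"]

#: Points closer than this (pixels) are treated as coincident.
DEGENERATE_EPS = 1e-6


class DegenerateGeometryError(ValueError):
    """Two of the three angle landmarks coincide."""


@dataclass(frozen=True)
class EarAngleResult:
    side: Literal["left", "right"]
    angle: float  # degrees in [0, 180]
    position: Position


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-centimeter conversion from the ear-tag fiducial."""

    tag_size_cm: float
    tag_extent_px: float

    def __post_init__(self) -> None:
        if self.tag_size_cm <= 0 or self.tag_extent_px <= 0:
            raise ValueError(
                f"tag size ({self.tag_size_cm} cm) and pixel extent "
                f"({self.tag_extent_px} px) must both be > 0"
            )

    @property
    def cm_per_px(self) -> float:
        return self.tag_size_cm / self.tag_extent_px


@dataclass
class FramePhenotypes:
    """Traits of one frame; ``None`` marks a trait whose landmarks were absent."""

    frame_index: int
    left_ear: Optional[EarAngleResult]
    right_ear: Optional[EarAngleResult]
    eye_opening_left_cm: Optional[float]
    eye_opening_right_cm: Optional[float]
    nostril_distance_cm: Optional[float]
    low_confidence: bool = False  # any used landmark was occluded (v=1)


def euclidean_distance(p: Point, q: Point) -> float:
    """Euclidean distance between two pixel points."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def ear_angle(ear_tip: Point, ear_base: Point, eye_ref: Point) -> float:
    """Angle in degrees at the ear base, by the law of cosines.

    Raises :class:`DegenerateGeometryError` when any two landmarks are
    closer than ``DEGENERATE_EPS`` pixels.  The cosine is clamped to
    [-1, 1] to absorb floating-point overshoot on near-collinear triples.
    """
    a = euclidean_distance(ear_base, ear_tip)
    c = euclidean_distance(ear_base, eye_ref)
    b = euclidean_distance(ear_tip, eye_ref)
    for name, d in (("tip/base", a), ("base/eye", c), ("tip/eye", b)):
        if d <= DEGENERATE_EPS:
            raise DegenerateGeometryError(
                f"coincident landmarks ({name}): separation {d:.2e} px"
            )
    cos_theta = (a * a + c * c - b * b) / (2.0 * a * c)
    cos_theta = max(-1.0, min(1.0, cos_theta))
    return math.degrees(math.acos(cos_theta))


def classify_ear_position(angle: float) -> Position:
    """Backward when the angle exceeds 90 degrees, frontward at or below."""
    if not 0.0 <= angle <= 180.0:
        raise ValueError(f"ear angle must be in [0, 180] degrees, got {angle}")
    return "backward" if angle > 90.0 else "frontward"


def paired_distance_cm(
    frame: KeypointFrame,
    label_a: str,
    label_b: str,
    cal: ScaleCalibration | None,
) -> Optional[float]:
    """Distance between two labeled keypoints in centimeters.

    Returns ``None`` (a missing trait, not an error) when either keypoint
    is absent from the frame.  ``cal=None`` raises — callers wanting pixel
    output should use :func:`euclidean_distance` directly.
    """
    if cal is None:
        raise ValueError(
            "no calibration given; use euclidean_distance for pixel-only output"
        )
    if not (frame.is_visible(label_a) and frame.is_visible(label_b)):
        return None
    return euclidean_distance(frame.points[label_a], frame.points[label_b]) * cal.cm_per_px


def _side_ear(frame: KeypointFrame, side: str) -> Optional[EarAngleResult]:
    tip, base, eye = f"{side}_ear_tip", f"{side}_ear_base", f"{side}_eye_top"
    if not all(frame.is_visible(l) for l in (tip, base, eye)):
        return None
    angle = ear_angle(frame.points[tip], frame.points[base], frame.points[eye])
    return EarAngleResult(side=side, angle=angle, position=classify_ear_position(angle))


def extract_frame_phenotypes(
    frame: KeypointFrame,
    cal: ScaleCalibration | None,
    schema: KeypointSchema = CALF_FACE_10,
) -> FramePhenotypes:
    """All per-frame traits; absent landmarks yield missing traits.

    Occluded landmarks (v=1) are used for geometry but the frame is
    flagged low-confidence.
    """
    return FramePhenotypes(
        frame_index=frame.frame_index,
        left_ear=_side_ear(frame, "left"),
        right_ear=_side_ear(frame, "right"),
        eye_opening_left_cm=paired_distance_cm(frame, "left_eye_top", "left_eye_bottom", cal),
        eye_opening_right_cm=paired_distance_cm(frame, "right_eye_top", "right_eye_bottom", cal),
        nostril_distance_cm=paired_distance_cm(frame, "left_nostril", "right_nostril", cal),
        low_confidence=any(frame.visibility.get(l, 0) == 1 for l in schema),
    )
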