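"""Synthetic calf-face keypoint trajectories with known ground truth.

Source videos of real calves are not publicly deposited, so every pipeline
stage is exercised on simulated head geometry instead.  The generator
emits the 10-landmark schema directly (no images are rendered):

* a rigid head template defined in centimeters — nostrils a fixed distance
  apart, upper/lower eyelid landmarks separated by the eye opening, fixed
  ear attachment points;
* two-state ear dynamics — each ear follows an independent two-state
  Markov chain (frontward/backward); the ear tip is placed by rotating the
  base-to-eye direction about the ear base so the ear angle equals the
  current state's mean angle plus Gaussian jitter;
* rendering to pixels — the template is scaled by ``scale_px_per_cm``,
  translated to the image center plus per-frame Gaussian camera jitter,
  and each keypoint is perturbed with isotropic Gaussian noise;
* a fiducial — the ear tag's pixel extent is ``tag_size_cm *
  scale_px_per_cm``, giving downstream code an exact calibration.

Ground truth (noise-free keypoints, latent ear states, true trait values)
is returned alongside the observed trajectory, so estimator error can be
measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import ScaleCalibration, classify_ear_position, ear_angle
from .schema import CALF_FACE_10, KeypointFrame, Trajectory
from .temporal import EarMovementCount, EarTimeBudget, count_transitions, time_in_position

__all__ = [
    "HeadModelParams",
    "GroundTruth",
    "simulate_trajectory",
    "corrupt_keypoints",
    "ParameterError",
]

Side = Literal["left", "right"]


class ParameterError(ValueError):
    """A generator parameter is outside its valid range."""


@dataclass(frozen=True)
class HeadModelParams:
    """Generator settings.

    Physical sizes are centimeters; the defaults place the synthetic
    population near the study herd (nostril distance 5.93 cm, eye openings
    2.75/2.76 cm) with ear dynamics whose stationary front fraction is
    about 0.64 and whose switch rate yields roughly 3.7 transitions per
    20-frame window.
    """

    scale_px_per_cm: float = 12.0
    nostril_distance_cm: float = 5.93
    eye_opening_cm: dict[Side, float] = field(
        default_factory=lambda: {"left": 2.75, "right": 2.76}
    )
    ear_front_angle_deg: float = 60.0
    ear_back_angle_deg: float = 120.0
    angle_jitter_sd_deg: float = 5.0
    p_front_to_back: float = 0.15
    p_back_to_front: float = 0.27
    keypoint_noise_sd_px: float = 1.0
    center_jitter_sd_px: float = 3.0
    tag_size_cm: float = 7.5
    ear_length_cm: float = 6.0
    image_size: tuple[int, int] = (640, 640)
    n_frames: int = 300
    frame_rate: float = 1.0
    initial_state: Side | str = "frontward"
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "scale_px_per_cm": self.scale_px_per_cm,
            "nostril_distance_cm": self.nostril_distance_cm,
            "tag_size_cm": self.tag_size_cm,
            "ear_length_cm": self.ear_length_cm,
            "frame_rate": self.frame_rate,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        for side in ("left", "right"):
            if self.eye_opening_cm.get(side, 0) <= 0:
                raise ParameterError(f"eye_opening_cm[{side!r}] must be > 0")
        for name, p in (
            ("p_front_to_back", self.p_front_to_back),
            ("p_back_to_front", self.p_back_to_front),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if not self.ear_front_angle_deg <= 90.0 < self.ear_back_angle_deg:
            raise ParameterError(
                "require ear_front_angle_deg <= 90 < ear_back_angle_deg, got "
                f"{self.ear_front_angle_deg} and {self.ear_back_angle_deg}"
            )
        if self.angle_jitter_sd_deg < 0 or self.keypoint_noise_sd_px < 0:
            raise ParameterError("angle_jitter_sd_deg / keypoint_noise_sd_px must be >= 0")
        if self.n_frames < 1:
            raise ParameterError(f"n_frames must be >= 1, got {self.n_frames}")


@dataclass
class GroundTruth:
    """Noise-free keypoints, latent states and true trait values."""

    true_trajectory: Trajectory
    ear_states: dict[Side, list[str]]  # latent Markov state per frame
    ear_angles_deg: dict[Side, list[float]]  # state mean + jitter, pre-noise
    ear_positions: dict[Side, list[str]]  # classification of the true angle
    time_budgets: dict[Side, EarTimeBudget]
    movement_windows: dict[Side, list[EarMovementCount]]
    calibration: ScaleCalibration
    nostril_distance_cm: float
    eye_opening_cm: dict[Side, float]


# Head-local template in cm: x rightward, y downward, origin mid-face.
_EYE_X = 4.0
_EYE_Y = 0.0
_EAR_BASE = {"left": (-6.0, -4.0), "right": (6.0, -4.0)}
_NOSTRIL_Y = 6.0


def _template_cm(params: HeadModelParams) -> dict[str, tuple[float, float]]:
    pts: dict[str, tuple[float, float]] = {}
    half_nostril = params.nostril_distance_cm / 2.0
    pts["left_nostril"] = (-half_nostril, _NOSTRIL_Y)
    pts["right_nostril"] = (half_nostril, _NOSTRIL_Y)
    for side, sign in (("left", -1.0), ("right", 1.0)):
        half_eye = params.eye_opening_cm[side] / 2.0
        pts[f"{side}_eye_top"] = (sign * _EYE_X, _EYE_Y - half_eye)
        pts[f"{side}_eye_bottom"] = (sign * _EYE_X, _EYE_Y + half_eye)
        pts[f"{side}_ear_base"] = _EAR_BASE[side]
    return pts


def _ear_tip_cm(
    template: dict[str, tuple[float, float]],
    side: Side,
    angle_deg: float,
    length_cm: float,
) -> tuple[float, float]:
    """Place the ear tip so the (tip, base, eye_top) angle equals ``angle_deg``.

    The base-to-eye direction is rotated about the base by the target
    angle; the rotation sense is mirrored between sides so that swapping
    left/right parameters mirrors the template exactly.
    """
    bx, by = template[f"{side}_ear_base"]
    ex, ey = template[f"{side}_eye_top"]
    ux, uy = ex - bx, ey - by
    norm = math.hypot(ux, uy)
    ux, uy = ux / norm, uy / norm
    theta = math.radians(angle_deg) * (1.0 if side == "left" else -1.0)
    rx = ux * math.cos(theta) - uy * math.sin(theta)
    ry = ux * math.sin(theta) + uy * math.cos(theta)
    return (bx + length_cm * rx, by + length_cm * ry)


def _simulate_states(
    rng: np.random.Generator, params: HeadModelParams
) -> dict[Side, list[str]]:
    states: dict[Side, list[str]] = {}
    for side in ("left", "right"):
        seq = []
        state = "frontward" if str(params.initial_state).startswith("front") else "backward"
        for _ in range(params.n_frames):
            seq.append(state)
            p = params.p_front_to_back if state == "frontward" else params.p_back_to_front
            if rng.random() < p:
                state = "backward" if state == "frontward" else "frontward"
        states[side] = seq
    return states


def _bbox(points: dict[str, tuple[float, float]], margin: float = 5.0):
    xs = [p[0] for p in points.values()]
    ys = [p[1] for p in points.values()]
    return (
        min(xs) - margin,
        min(ys) - margin,
        max(xs) - min(xs) + 2 * margin,
        max(ys) - min(ys) + 2 * margin,
    )


def simulate_trajectory(params: HeadModelParams) -> tuple[Trajectory, GroundTruth]:
    """Generate one observed trajectory and its ground truth.

    Deterministic given ``params.seed``.  The observed trajectory carries
    keypoint noise; the ground truth holds the noise-free frames, the
    latent ear states, and the true trait values (time budgets and
    movement windows computed from the true ear positions).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    template = _template_cm(params)
    states = _simulate_states(rng, params)
    scale = params.scale_px_per_cm
    cx, cy = params.image_size[0] / 2.0, params.image_size[1] / 2.0

    true_frames: list[KeypointFrame] = []
    noisy_frames: list[KeypointFrame] = []
    angles: dict[Side, list[float]] = {"left": [], "right": []}
    positions: dict[Side, list[str]] = {"left": [], "right": []}

    for t in range(params.n_frames):
        frame_pts_cm = dict(template)
        for side in ("left", "right"):
            mean = (
                params.ear_front_angle_deg
                if states[side][t] == "frontward"
                else params.ear_back_angle_deg
            )
            angle = float(
                np.clip(mean + rng.normal(0.0, params.angle_jitter_sd_deg), 1.0, 179.0)
            )
            angles[side].append(angle)
            positions[side].append(classify_ear_position(angle))
            frame_pts_cm[f"{side}_ear_tip"] = _ear_tip_cm(
                frame_pts_cm, side, angle, params.ear_length_cm
            )

        dx, dy = rng.normal(0.0, params.center_jitter_sd_px, size=2)
        true_pts = {
            label: (cx + dx + x * scale, cy + dy + y * scale)
            for label, (x, y) in frame_pts_cm.items()
        }
        vis = {label: 2 for label in CALF_FACE_10}
        true_frames.append(
            KeypointFrame(
                frame_index=t,
                points=dict(true_pts),
                visibility=dict(vis),
                image_size=params.image_size,
                bbox=_bbox(true_pts),
            )
        )
        noise = rng.normal(0.0, params.keypoint_noise_sd_px, size=(len(CALF_FACE_10), 2))
        noisy_pts = {
            label: (true_pts[label][0] + noise[i, 0], true_pts[label][1] + noise[i, 1])
            for i, label in enumerate(CALF_FACE_10)
        }
        noisy_frames.append(
            KeypointFrame(
                frame_index=t,
                points=noisy_pts,
                visibility=dict(vis),
                image_size=params.image_size,
                bbox=_bbox(noisy_pts),
            )
        )

    calibration = ScaleCalibration(
        tag_size_cm=params.tag_size_cm, tag_extent_px=params.tag_size_cm * scale
    )
    truth = GroundTruth(
        true_trajectory=Trajectory(
            animal_id="sim", session_id=f"seed{params.seed}",
            frames=true_frames, frame_rate=params.frame_rate,
        ),
        ear_states=states,
        ear_angles_deg=angles,
        ear_positions=positions,
        time_budgets={
            side: time_in_position(positions[side], params.frame_rate, side=side)
            for side in ("left", "right")
        },
        movement_windows={
            side: count_transitions(positions[side], side=side)
            for side in ("left", "right")
        },
        calibration=calibration,
        nostril_distance_cm=params.nostril_distance_cm,
        eye_opening_cm=dict(params.eye_opening_cm),
    )
    observed = Trajectory(
        animal_id="sim", session_id=f"seed{params.seed}",
        frames=noisy_frames, frame_rate=params.frame_rate,
    )
    return observed, truth


def corrupt_keypoints(
    truth: Trajectory, displacement_sd_px: float, drop_prob: float, seed: int
) -> Trajectory:
    """Degrade a trajectory into a mock prediction.

    Each labeled keypoint is displaced by isotropic Gaussian noise of the
    given SD; independently, with probability ``drop_prob`` its visibility
    is set to 0.  Deterministic given ``seed``.
    """
    if displacement_sd_px < 0:
        raise ParameterError(f"displacement_sd_px must be >= 0, got {displacement_sd_px}")
    if not 0.0 <= drop_prob <= 1.0:
        raise ParameterError(f"drop_prob must be in [0, 1], got {drop_prob}")
    rng = np.random.default_rng(seed)
    frames = []
    for frame in truth:
        points, visibility = {}, {}
        for label, (x, y) in frame.points.items():
            dx, dy = rng.normal(0.0, displacement_sd_px, size=2)
            points[label] = (x + dx, y + dy)
            v = frame.visibility[label]
            if v > 0 and rng.random() < drop_prob:
                v = 0
            visibility[label] = v
        frames.append(
            KeypointFrame(
                frame_index=frame.frame_index,
                points=points,
                visibility=visibility,
                image_size=frame.image_size,
                bbox=frame.bbox,
            )
        )
    return Trajectory(
        animal_id=truth.animal_id,
        session_id=truth.session_id,
        frames=frames,
        frame_rate=truth.frame_rate,
    )
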