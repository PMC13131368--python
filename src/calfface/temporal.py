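"""Temporal aggregation of ear posture: time budgets and movement counts.

Time in position: each frame with a defined posture contributes
``1 / frame_rate`` seconds to that posture's total; frames with a missing
posture contribute to neither, so ``time_front + time_back`` equals the
defined-frame count divided by the frame rate.

Ear movement: a movement is a transition between frontward and backward
posture on consecutive frames, and is counted only when at least 20
consecutive defined frames are available (20 s at 1 fps).  The posture
sequence is cut at missing frames into maximal runs; each qualifying run
is tiled with non-overlapping windows of ``min_window`` frames from the
run start (a sliding mode is available), trailing partial windows are
dropped, and transitions are counted within each window.  No transition is
ever counted across a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

__all__ = [
    "EarTimeBudget",
    "EarMovementCount",
    "time_in_position",
    "count_transitions",
    "MIN_MOVEMENT_WINDOW",
]

Position = Optional[Literal["frontward", "backward"]]

#: Movement is quantified only over runs of at least this many consecutive
#: defined frames (20 frames = 20 s at the 1 fps sampling rate).
MIN_MOVEMENT_WINDOW = 20


@dataclass
class EarTimeBudget:
    side: str
    time_front: float  # seconds
    time_back: float  # seconds
    n_frames: int  # frames with a defined position
    frame_rate: float


@dataclass
class EarMovementCount:
    side: str
    window_start: int  # index into the position sequence
    n_transitions: int
    window_len: int


def time_in_position(
    positions: Sequence[Position], frame_rate: float = 1.0, side: str = ""
) -> EarTimeBudget:
    """Seconds spent frontward and backward over a posture sequence."""
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be > 0, got {frame_rate}")
    if len(positions) == 0:
        raise ValueError("empty position sequence")
    n_front = sum(1 for p in positions if p == "frontward")
    n_back = sum(1 for p in positions if p == "backward")
    return EarTimeBudget(
        side=side,
        time_front=n_front / frame_rate,
        time_back=n_back / frame_rate,
        n_frames=n_front + n_back,
        frame_rate=frame_rate,
    )


def _runs(positions: Sequence[Position]) -> list[tuple[int, list[str]]]:
    """Maximal runs of consecutive defined positions as (start, values)."""
    runs: list[tuple[int, list[str]]] = []
    current: list[str] = []
    start = 0
    for i, p in enumerate(positions):
        if p is None:
            if current:
                runs.append((start, current))
                current = []
        else:
            if not current:
                start = i
            current.append(p)
    if current:
        runs.append((start, current))
    return runs


def count_transitions(
    positions: Sequence[Position],
    min_window: int = MIN_MOVEMENT_WINDOW,
    side: str = "",
    window_mode: Literal["tumbling", "sliding"] = "tumbling",
) -> list[EarMovementCount]:
    """Per-window ear-movement counts under the consecutive-frame rule.

    Returns one :class:`EarMovementCount` per qualifying window; a sequence
    with no run of ``min_window`` defined frames yields an empty list.  In
    ``tumbling`` mode (default) windows within a run are non-overlapping so
    no transition is counted twice; ``sliding`` advances one frame at a
    time.
    """
    if min_window < 2:
        raise ValueError(f"min_window must be >= 2, got {min_window}")
    out: list[EarMovementCount] = []
    step = min_window if window_mode == "tumbling" else 1
    for start, run in _runs(positions):
        for off in range(0, len(run) - min_window + 1, step):
            window = run[off : off + min_window]
            n = sum(1 for a, b in zip(window, window[1:]) if a != b)
            out.append(
                EarMovementCount(
                    side=side,
                    window_start=start + off,
                    n_transitions=n,
                    window_len=min_window,
                )
            )
    return out
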