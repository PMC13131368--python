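"""Object keypoint similarity (OKS) evaluation.

OKS compares a predicted keypoint set against ground truth, normalizing
each displacement by the object scale and a per-keypoint tolerance
constant:

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

where ``d_i`` is the Euclidean pixel displacement of keypoint ``i``,
``s^2`` the object area in squared pixels, ``k_i`` the per-keypoint
constant, and ``v_i`` the ground-truth visibility.  Keypoints absent from
the ground truth contribute to neither sum.

A sweep over OKS thresholds (0.50 to 0.95 in steps of 0.05) classifies
each scored prediction as a true positive (OKS at or above the threshold)
or false positive (below), from which per-threshold precision/recall and
their sweep means (AP, AR) are derived.  Frames here hold a single animal,
so each prediction is matched to its frame's ground truth with no
assignment step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import KeypointFrame, KeypointSchema

__all__ = [
    "DEFAULT_KAPPA",
    "DEFAULT_THRESHOLDS",
    "OksRecord",
    "ThresholdMetrics",
    "EvalReport",
    "compute_oks",
    "classify_at_threshold",
    "evaluate",
    "f1_score",
    "object_area",
    "UndefinedOksError",
]

#: Uniform per-keypoint constant.  No calf-face constants are established;
#: 0.05 is of the magnitude used for fine facial landmarks in the OKS
#: literature and keeps all landmarks exchangeable.  Override per label via
#: the ``kappas`` argument or the pipeline config.
DEFAULT_KAPPA = 0.05

#: COCO-style threshold sweep, 0.50:0.05:0.95.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


class UndefinedOksError(ValueError):
    """OKS is undefined: no visible ground-truth keypoint."""


@dataclass
class OksRecord:
    instance_id: str
    oks: float
    per_keypoint_terms: dict[str, float]
    area: float
    n_visible: int


@dataclass
class ThresholdMetrics:
    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float


@dataclass
class EvalReport:
    per_threshold: list[ThresholdMetrics]
    ap_mean: float
    ar_mean: float
    ap_at: dict[float, float]
    ar_at: dict[float, float]
    f1: float

    def to_frame(self) -> pd.DataFrame:
        """Per-threshold metrics plus a summary row, in Table-1-like shape."""
        rows = [
            {
                "threshold": m.threshold,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": m.precision,
                "recall": m.recall,
            }
            for m in self.per_threshold
        ]
        rows.append(
            {
                "threshold": "mean(AP/AR)",
                "tp": "",
                "fp": "",
                "fn": "",
                "precision": self.ap_mean,
                "recall": self.ar_mean,
            }
        )
        return pd.DataFrame(rows)


def object_area(frame: KeypointFrame, schema: KeypointSchema) -> float:
    """Object scale s^2 in squared pixels.

    Uses the bounding-box area when a bbox is present, otherwise the area
    of the axis-aligned bounding box of the labeled keypoints.
    """
    if frame.bbox is not None:
        area = frame.bbox[2] * frame.bbox[3]
    else:
        pts = [frame.points[l] for l in schema if frame.visibility[l] > 0]
        if not pts:
            raise UndefinedOksError("no labeled keypoints to derive an object area from")
        xs, ys = zip(*pts)
        area = (max(xs) - min(xs)) * (max(ys) - min(ys))
    if area <= 0:
        raise ValueError(f"object area must be > 0, got {area}")
    return area


def compute_oks(
    pred: KeypointFrame,
    truth: KeypointFrame,
    kappas: Mapping[str, float] | float = DEFAULT_KAPPA,
    area: float | None = None,
    schema: KeypointSchema | None = None,
    instance_id: str = "",
) -> OksRecord:
    """Score one predicted frame against its ground truth.

    ``kappas`` is either a single constant applied to every label or a
    label→constant mapping; labels in the frames but not in the schema are
    ignored, so inputs carrying extra landmarks score only the shared set.
    ``area`` defaults to :func:`object_area` of the truth frame.
    """
    if schema is None:
        labels = [l for l in truth.points if l in pred.points]
    else:
        labels = list(schema.names)
    if area is None:
        area = object_area(truth, schema) if schema is not None else _area_from_labels(truth, labels)
    if area <= 0:
        raise ValueError(f"object area must be > 0, got {area}")

    terms: dict[str, float] = {}
    for label in labels:
        if truth.visibility.get(label, 0) <= 0:
            continue
        k = kappas[label] if isinstance(kappas, Mapping) else float(kappas)
        px, py = pred.points[label]
        tx, ty = truth.points[label]
        d2 = (px - tx) ** 2 + (py - ty) ** 2
        terms[label] = math.exp(-d2 / (2.0 * area * k * k))
    if not terms:
        raise UndefinedOksError(
            "OKS undefined: ground truth has no visible keypoint among "
            f"{len(labels)} schema labels"
        )
    return OksRecord(
        instance_id=instance_id,
        oks=sum(terms.values()) / len(terms),
        per_keypoint_terms=terms,
        area=float(area),
        n_visible=len(terms),
    )


def _area_from_labels(frame: KeypointFrame, labels: Sequence[str]) -> float:
    if frame.bbox is not None:
        area = frame.bbox[2] * frame.bbox[3]
    else:
        pts = [frame.points[l] for l in labels if frame.visibility.get(l, 0) > 0]
        if not pts:
            raise UndefinedOksError("no labeled keypoints to derive an object area from")
        xs, ys = zip(*pts)
        area = (max(xs) - min(xs)) * (max(ys) - min(ys))
    if area <= 0:
        raise ValueError(f"object area must be > 0, got {area}")
    return area


def classify_at_threshold(
    scores: Sequence[OksRecord], threshold: float, n_truth: int | None = None
) -> ThresholdMetrics:
    """Classify scored predictions at one OKS threshold.

    A score at or above the threshold is a true positive ("within the
    threshold"); below is a false positive.  ``n_truth`` is the number of
    ground-truth instances; truths with no scored prediction count as false
    negatives.  With one prediction per truth (the single-calf setting)
    recall equals precision at every threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not scores:
        raise ValueError("empty score list: nothing to classify")
    if n_truth is None:
        n_truth = len(scores)
    tp = sum(1 for r in scores if r.oks >= threshold)
    fp = len(scores) - tp
    fn = n_truth - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_truth if n_truth else 0.0
    return ThresholdMetrics(
        threshold=threshold, tp=tp, fp=fp, fn=fn, precision=precision, recall=recall
    )


def evaluate(
    pairs: Sequence[tuple[KeypointFrame, KeypointFrame]],
    kappas: Mapping[str, float] | float = DEFAULT_KAPPA,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    schema: KeypointSchema | None = None,
) -> EvalReport:
    """Score (pred, truth) pairs and sweep the OKS thresholds.

    AP and AR are the arithmetic means of per-threshold precision and
    recall over the sweep; ``ap_at``/``ar_at`` expose the named cuts (0.75,
    0.95 by default).  F1 is the harmonic mean of AP and AR.
    """
    if not pairs:
        raise ValueError("evaluate requires at least one (pred, truth) pair")
    scores = [
        compute_oks(pred, truth, kappas=kappas, schema=schema, instance_id=str(i))
        for i, (pred, truth) in enumerate(pairs)
    ]
    per_threshold = [classify_at_threshold(scores, t, n_truth=len(pairs)) for t in thresholds]
    ap_mean = float(np.mean([m.precision for m in per_threshold]))
    ar_mean = float(np.mean([m.recall for m in per_threshold]))
    return EvalReport(
        per_threshold=per_threshold,
        ap_mean=ap_mean,
        ar_mean=ar_mean,
        ap_at={m.threshold: m.precision for m in per_threshold},
        ar_at={m.threshold: m.recall for m in per_threshold},
        f1=f1_score(ap_mean, ar_mean),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)
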