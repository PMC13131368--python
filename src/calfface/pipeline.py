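"""End-to-end orchestration: dataset splitting, per-session phenotype
extraction, descriptive summaries, and the run driver behind the CLI.

Per-session phenotypes are the temporal aggregates of the per-frame
geometry: mean facial distances in cm, per-ear time budgets in seconds,
and ear-movement counts under the 20-consecutive-frame rule.  The summary
table reports min / mean / max / sample SD / CV(%) per trait across
sessions; time budgets and movement counts are pooled over the two ears
for the summary (per-ear columns remain in the phenotype table).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import keypoint_io
from .geometry import ScaleCalibration, extract_frame_phenotypes
from .oks import DEFAULT_KAPPA, DEFAULT_THRESHOLDS, EvalReport, evaluate
from .schema import CALF_FACE_10, KeypointSchema, Trajectory
from .temporal import MIN_MOVEMENT_WINDOW, count_transitions, time_in_position

__all__ = [
    "PhenotypeRecord",
    "SummaryRow",
    "SplitAssignment",
    "PHENOTYPE_COLUMNS",
    "group_split",
    "holdout_count",
    "summarize",
    "summary_table",
    "extract_trajectory_phenotypes",
    "phenotype_summary",
    "run_pipeline",
    "PipelineConfig",
]

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = (
    "animal_id",
    "session_id",
    "n_frames",
    "nostril_distance_cm",
    "eye_opening_left_cm",
    "eye_opening_right_cm",
    "time_front_left_s",
    "time_back_left_s",
    "time_front_right_s",
    "time_back_right_s",
    "ear_movement_left_count",
    "ear_movement_right_count",
    "ear_movement_per_window",
)


@dataclass
class PhenotypeRecord:
    """Per-session extracted traits; ``None`` marks an unavailable trait."""

    animal_id: str
    session_id: str
    n_frames: int
    nostril_distance_cm: Optional[float]
    eye_opening_left_cm: Optional[float]
    eye_opening_right_cm: Optional[float]
    time_front_left_s: float
    time_back_left_s: float
    time_front_right_s: float
    time_back_right_s: float
    ear_movement_left_count: Optional[int]
    ear_movement_right_count: Optional[int]
    ear_movement_per_window: Optional[float]

    def as_row(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in PHENOTYPE_COLUMNS}


@dataclass
class SummaryRow:
    item: str
    minimum: float
    mean: float
    maximum: float
    sd: float
    cv_percent: Optional[int]  # nearest-integer 100*sd/mean; None if mean <= 0


@dataclass(frozen=True)
class SplitAssignment:
    unit_id: str  # image id
    animal_id: str
    subset: str


def holdout_count(total: int, train_fraction: float) -> tuple[int, int]:
    """Split a total image count into (train, predict) by a fraction.

    Nearest-integer rounding of ``total * train_fraction``; the remainder
    is retained for prediction, so the two counts always sum to the total.
    """
    if total <= 0:
        raise ValueError(f"total must be > 0, got {total}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    train = round(total * train_fraction)
    return train, total - train


def group_split(
    units: Sequence[tuple[str, str]],
    fractions: Mapping[str, float],
    seed: int,
) -> list[SplitAssignment]:
    """Animal-grouped split of (image_id, animal_id) units.

    Whole animals are assigned to subsets so that image-count proportions
    approximate the target fractions; no animal ever spans subsets and
    every image lands in exactly one subset.  Deterministic given the
    seed: animals are shuffled, then assigned greedily to the subset whose
    image deficit (target minus current share) is largest.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {dict(fractions)}")
    animals: dict[str, list[str]] = {}
    for image_id, animal_id in units:
        animals.setdefault(animal_id, []).append(image_id)
    if len(fractions) > len(animals):
        raise ValueError(
            f"infeasible split: {len(fractions)} subsets but only "
            f"{len(animals)} animals"
        )
    total = len(units)
    rng = np.random.default_rng(seed)
    order = sorted(animals)
    rng.shuffle(order)
    # seed each subset with one animal so none is empty, largest target first
    subsets = sorted(fractions, key=lambda s: -fractions[s])
    counts = {s: 0 for s in subsets}
    assignment: dict[str, str] = {}
    for i, animal in enumerate(order):
        if i < len(subsets):
            chosen = subsets[i]
        else:
            chosen = max(subsets, key=lambda s: fractions[s] * total - counts[s])
        assignment[animal] = chosen
        counts[chosen] += len(animals[animal])
    return [
        SplitAssignment(unit_id=image_id, animal_id=animal_id, subset=assignment[animal_id])
        for image_id, animal_id in units
    ]


def summarize(values: Sequence[float], item: str) -> SummaryRow:
    """Min / mean / max / sample SD / CV(%) of one trait across sessions.

    SD uses the n-1 denominator; CV = 100 * SD / mean rounded to the
    nearest integer percent, reported as missing when the mean is not
    positive.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        raise ValueError(f"no values to summarize for {item!r}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = round(100.0 * sd / mean) if mean > 0 else None
    return SummaryRow(
        item=item,
        minimum=float(vals.min()),
        mean=mean,
        maximum=float(vals.max()),
        sd=sd,
        cv_percent=cv,
    )


def summary_table(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "item": r.item,
                "minimum": r.minimum,
                "mean": r.mean,
                "maximum": r.maximum,
                "sd": r.sd,
                "cv_percent": r.cv_percent,
            }
            for r in rows
        ]
    )


def extract_trajectory_phenotypes(
    traj: Trajectory,
    cal: ScaleCalibration | None,
    min_window: int = MIN_MOVEMENT_WINDOW,
    schema: KeypointSchema = CALF_FACE_10,
    window_mode: Literal["tumbling", "sliding"] = "tumbling",
) -> PhenotypeRecord:
    """Aggregate one session's frames into a phenotype record.

    Distances are averaged over frames where they are defined; ear time
    budgets and movement windows follow the temporal rules with missing
    postures breaking runs.  Skipped traits are logged with a reason.
    """
    per_frame = [extract_frame_phenotypes(f, cal, schema=schema) for f in traj]
    n_skipped = sum(
        1 for p in per_frame
        if p.nostril_distance_cm is None or p.left_ear is None or p.right_ear is None
    )
    if n_skipped:
        log.info(
            "%s/%s: %d of %d frames missing at least one trait (absent keypoints)",
            traj.animal_id, traj.session_id, n_skipped, len(per_frame),
        )

    def _mean(vals: list[Optional[float]]) -> Optional[float]:
        defined = [v for v in vals if v is not None]
        return float(np.mean(defined)) if defined else None

    positions = {
        "left": [p.left_ear.position if p.left_ear else None for p in per_frame],
        "right": [p.right_ear.position if p.right_ear else None for p in per_frame],
    }
    budgets = {
        s: time_in_position(positions[s], traj.frame_rate, side=s) for s in positions
    }
    windows = {
        s: count_transitions(positions[s], min_window=min_window, side=s,
                             window_mode=window_mode)
        for s in positions
    }
    n_windows = sum(len(w) for w in windows.values())
    all_counts = [w.n_transitions for ws in windows.values() for w in ws]
    return PhenotypeRecord(
        animal_id=traj.animal_id,
        session_id=traj.session_id,
        n_frames=len(traj),
        nostril_distance_cm=_mean([p.nostril_distance_cm for p in per_frame]),
        eye_opening_left_cm=_mean([p.eye_opening_left_cm for p in per_frame]),
        eye_opening_right_cm=_mean([p.eye_opening_right_cm for p in per_frame]),
        time_front_left_s=budgets["left"].time_front,
        time_back_left_s=budgets["left"].time_back,
        time_front_right_s=budgets["right"].time_front,
        time_back_right_s=budgets["right"].time_back,
        ear_movement_left_count=(
            sum(w.n_transitions for w in windows["left"]) if windows["left"] else None
        ),
        ear_movement_right_count=(
            sum(w.n_transitions for w in windows["right"]) if windows["right"] else None
        ),
        ear_movement_per_window=(
            float(np.mean(all_counts)) if n_windows else None
        ),
    )


#: Traits summarized across sessions, pooling the two ears where the
#: phenotype table keeps them separate.
def phenotype_summary(records: Sequence[PhenotypeRecord]) -> list[SummaryRow]:
    def pool(attr_left: str, attr_right: str) -> list[float]:
        out = []
        for r in records:
            for attr in (attr_left, attr_right):
                v = getattr(r, attr)
                if v is not None:
                    out.append(v)
        return out

    def col(attr: str) -> list[float]:
        return [getattr(r, attr) for r in records if getattr(r, attr) is not None]

    rows = []
    for item, values in (
        ("nostril_distance_cm", col("nostril_distance_cm")),
        ("eye_opening_right_cm", col("eye_opening_right_cm")),
        ("eye_opening_left_cm", col("eye_opening_left_cm")),
        ("time_ear_front_s", pool("time_front_left_s", "time_front_right_s")),
        ("time_ear_back_s", pool("time_back_left_s", "time_back_right_s")),
        ("ear_movement_count", pool("ear_movement_left_count", "ear_movement_right_count")),
    ):
        if values:
            rows.append(summarize(values, item))
        else:
            log.warning("summary row %r skipped: no defined values", item)
    return rows


@dataclass
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    ``mode`` selects evaluation (OKS sweep on pred/truth pairs),
    phenotyping, or both.  ``tag_size_cm`` with ``tag_extent_px`` defines
    the calibration; leave both unset for pixel-only trait extraction
    (distances then stay in pixels and are labeled as such in the log).
    """

    mode: Literal["evaluate", "phenotype", "both"] = "phenotype"
    input_paths: list[str] = field(default_factory=list)  # COCO JSON, one per session
    pred_path: Optional[str] = None
    truth_path: Optional[str] = None
    out_dir: str = "."
    tag_size_cm: Optional[float] = None
    tag_extent_px: Optional[float] = None
    frame_rate: float = 1.0
    min_window: int = MIN_MOVEMENT_WINDOW
    window_mode: Literal["tumbling", "sliding"] = "tumbling"
    kappa: float = DEFAULT_KAPPA
    kappas: Optional[dict[str, float]] = None
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_trajectory(path: str, frame_rate: float, schema: KeypointSchema) -> Trajectory:
    pairs = keypoint_io.read_coco_keypoints(path, schema)
    return Trajectory(
        animal_id=Path(path).stem,
        session_id=Path(path).stem,
        frames=[frame for _, frame in pairs],
        frame_rate=frame_rate,
    )


def run_pipeline(config: PipelineConfig, schema: KeypointSchema = CALF_FACE_10):
    """Run the configured stages and write CSV outputs plus a run log.

    Outputs under ``config.out_dir``: ``phenotypes.csv`` (one row per
    session), ``summary.csv`` (one row per trait), ``eval_report.csv``
    (one row per OKS threshold) when evaluating, and ``run_log.json``.
    Deterministic: identical inputs and config give byte-identical tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    records: list[PhenotypeRecord] = []
    report: Optional[EvalReport] = None

    if config.mode in ("phenotype", "both"):
        if not config.input_paths:
            raise ValueError("phenotype mode requires input_paths in the config")
        for p in config.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        cal = None
        if config.tag_size_cm is not None and config.tag_extent_px is not None:
            cal = ScaleCalibration(config.tag_size_cm, config.tag_extent_px)
        else:
            log.warning("no ear-tag calibration: distance traits left in pixels")
        for path in config.input_paths:
            traj = _load_trajectory(path, config.frame_rate, schema)
            records.append(
                extract_trajectory_phenotypes(
                    traj, cal, min_window=config.min_window, schema=schema,
                    window_mode=config.window_mode,
                )
            )
        keypoint_io.write_phenotype_table(
            [r.as_row() for r in records], out_dir / "phenotypes.csv"
        )
        written["phenotypes"] = str(out_dir / "phenotypes.csv")
        rows = phenotype_summary(records)
        summary_table(rows).to_csv(out_dir / "summary.csv", index=False)
        written["summary"] = str(out_dir / "summary.csv")

    if config.mode in ("evaluate", "both"):
        if not (config.pred_path and config.truth_path):
            raise ValueError("evaluate mode requires pred_path and truth_path")
        for p in (config.pred_path, config.truth_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        pred = {i: f for i, f in keypoint_io.read_coco_keypoints(config.pred_path, schema)}
        truth = {i: f for i, f in keypoint_io.read_coco_keypoints(config.truth_path, schema)}
        shared = sorted(set(pred) & set(truth))
        if not shared:
            raise ValueError("pred and truth share no image ids")
        kappas = config.kappas if config.kappas else config.kappa
        report = evaluate(
            [(pred[i], truth[i]) for i in shared],
            kappas=kappas,
            thresholds=config.thresholds,
            schema=schema,
        )
        report.to_frame().to_csv(out_dir / "eval_report.csv", index=False)
        written["eval_report"] = str(out_dir / "eval_report.csv")

    from . import __version__

    config_json = json.dumps(asdict(config), sort_keys=True)
    run_log = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {"calfface": __version__, "pandas": pd.__version__,
                     "numpy": np.__version__},
        "n_sessions": len(records),
        "n_frames": sum(r.n_frames for r in records),
        "outputs": written,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    return records, report
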