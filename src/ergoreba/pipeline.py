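"""Frame loop, temporal activity detection and procedure-level aggregation.

A landmark sequence is scored frame by frame — validate, extract joint
angles, apply the REBA worksheet — and the per-frame integer scores are
averaged arithmetically into a procedure-level mean REBA. Averaging scores
(rather than scoring averaged angles) is what yields the familiar
non-integer procedure scores such as 2.58.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .kinematics import (
    DEFAULT_KINEMATICS,
    DegenerateGeometryError,
    JointAngles,
    KinematicsConfig,
    compute_joint_angles,
)
from .pose_model import LandmarkSequence, PoseFrame, validate_frame
from .reba import (
    DEFAULT_SCORING,
    RebaAdjustments,
    RebaResult,
    ScoringConfig,
    compute_reba,
)
from .topology import get_topology


@dataclass(frozen=True)
class ActivityConfig:
    """Temporal activity-adjustment detection.

    mode: "auto" applies the windowed rules below; "off" pins the activity
    score to 0 (useful when table lookups should fully determine scores);
    "fixed" uses ``fixed_score``.
    """

    mode: str = "auto"
    fixed_score: int = 0
    window_s: float = 60.0
    static_range_deg: float = 5.0
    reversal_rate_per_min: float = 4.0
    #: steps smaller than this are not counted as reversals (numerical floor)
    reversal_min_step_deg: float = 1.0
    rapid_change_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "off", "fixed"):
            raise ValueError(f"activity mode must be auto/off/fixed, got {self.mode!r}")
        if not (0 <= self.fixed_score <= 3):
            raise ValueError("fixed_score must be in [0, 3]")


@dataclass(frozen=True)
class PipelineConfig:
    kinematics: KinematicsConfig = DEFAULT_KINEMATICS
    scoring: ScoringConfig = DEFAULT_SCORING
    activity: ActivityConfig = ActivityConfig()
    load_score: int = 0
    coupling_score: int = 0
    #: refuse to report a mean when fewer than this fraction of frames scored
    min_scored_fraction: float = 0.10

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_PIPELINE = PipelineConfig()


@dataclass(frozen=True)
class FrameScore:
    frame_index: int
    timestamp_s: float
    usable: bool
    joint_angles: Optional[JointAngles] = None
    reba_result: Optional[RebaResult] = None
    drop_reason: str = ""


class ReportError(ValueError):
    """A procedure report could not be produced."""


@dataclass
class ProcedureReport:
    """Aggregation of one scored landmark sequence."""

    subject_id: str
    condition: str
    n_frames_total: int
    n_frames_scored: int
    mean_reba: float
    per_joint_means: dict[str, float]
    frame_scores: list[FrameScore]
    config_snapshot: dict

    @property
    def reba_time_series(self) -> list[tuple[int, int]]:
        return [
            (fs.frame_index, fs.reba_result.reba)
            for fs in self.frame_scores
            if fs.usable and fs.reba_result is not None
        ]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "subject_id": self.subject_id,
            "condition": self.condition,
            "n_frames_total": self.n_frames_total,
            "n_frames_scored": self.n_frames_scored,
            "mean_reba": self.mean_reba,
            "per_joint_means": self.per_joint_means,
            "reba_time_series": self.reba_time_series,
            "dropped_frames": [
                {"frame_index": fs.frame_index, "reason": fs.drop_reason}
                for fs in self.frame_scores
                if not fs.usable
            ],
            "config": self.config_snapshot,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")
        return path


def score_frame(
    frame: PoseFrame,
    config: PipelineConfig = DEFAULT_PIPELINE,
    topology: str = "blazepose_33",
    activity_score: int = 0,
) -> FrameScore:
    """Validate, extract angles and score one frame.

    Never raises per-frame: unusable or degenerate frames come back with
    ``usable=False`` and a drop reason.
    """
    check = validate_frame(
        frame, get_topology(topology), config.kinematics.min_visibility
    )
    if not check.usable:
        return FrameScore(
            frame_index=frame.frame_index,
            timestamp_s=frame.timestamp_s,
            usable=False,
            drop_reason=f"missing landmarks: {', '.join(check.missing)}",
        )
    try:
        angles = compute_joint_angles(frame, config.kinematics)
        result = compute_reba(
            angles,
            RebaAdjustments(
                load_score=config.load_score,
                coupling_score=config.coupling_score,
                activity_score=activity_score,
            ),
            config.scoring,
        )
    except DegenerateGeometryError as exc:
        return FrameScore(
            frame_index=frame.frame_index,
            timestamp_s=frame.timestamp_s,
            usable=False,
            drop_reason=str(exc),
        )
    return FrameScore(
        frame_index=frame.frame_index,
        timestamp_s=frame.timestamp_s,
        usable=True,
        joint_angles=angles,
        reba_result=result,
    )


def detect_activity(
    window: list[FrameScore],
    config: ActivityConfig = ActivityConfig(),
) -> int:
    """Activity adjustment (0-3) from a window of scored frames.

    +1 if the posture is static (every tracked angle spans < the static
    range over a full-length window); +1 if small-range action reversals
    exceed the configured rate; +1 if any angle jumps more than the rapid
    threshold between consecutive frames. Capped at 3.
    """
    usable = [fs for fs in window if fs.usable and fs.joint_angles is not None]
    if len(usable) < 2:
        return 0
    duration = usable[-1].timestamp_s - usable[0].timestamp_s
    names = sorted(usable[0].joint_angles.tracked())
    series = {
        k: np.array([fs.joint_angles.tracked().get(k, np.nan) for fs in usable])
        for k in names
    }
    score = 0
    if duration >= config.window_s:
        if all(
            np.nanmax(v) - np.nanmin(v) < config.static_range_deg
            for v in series.values() if np.isfinite(v).any()
        ):
            score += 1
    # direction reversals of any tracked angle, per minute
    if duration > 0:
        reversals = 0
        for v in series.values():
            d = np.diff(v[np.isfinite(v)])
            d = d[np.abs(d) >= config.reversal_min_step_deg]
            if len(d) > 1:
                reversals += int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
        if reversals / (duration / 60.0) > config.reversal_rate_per_min:
            score += 1
    if any(
        np.nanmax(np.abs(np.diff(v))) > config.rapid_change_deg
        for v in series.values() if len(v) > 1
    ):
        score += 1
    return min(score, 3)


_JOINT_GROUPS = (
    "neck", "trunk", "legs",
    "upper_arm_left", "upper_arm_right",
    "lower_arm_left", "lower_arm_right",
    "wrist_left", "wrist_right",
)


def score_sequence(
    seq: LandmarkSequence,
    config: PipelineConfig = DEFAULT_PIPELINE,
) -> ProcedureReport:
    """Score every frame of a sequence and aggregate.

    mean_reba is the arithmetic mean of per-frame integer REBA scores over
    the scored frames; per-joint means are computed the same way from the
    sub-scores. Deterministic: identical inputs produce identical reports.
    """
    if config.kinematics.smoothing_window > 1:
        from .pose_model import smooth_landmarks

        seq = smooth_landmarks(seq, config.kinematics.smoothing_window)
    act_cfg = config.activity
    # first pass without activity, to feed the temporal detector
    prelim = [
        score_frame(fr, config, seq.topology, activity_score=0)
        for fr in seq.frames
    ]
    scores: list[FrameScore] = []
    for i, (fr, p) in enumerate(zip(seq.frames, prelim)):
        if not p.usable:
            scores.append(p)
            continue
        if act_cfg.mode == "off":
            activity = 0
        elif act_cfg.mode == "fixed":
            activity = act_cfg.fixed_score
        else:
            t0 = fr.timestamp_s - act_cfg.window_s
            window = [q for q in prelim[: i + 1] if q.timestamp_s >= t0]
            activity = detect_activity(window, act_cfg)
        if activity == 0:
            scores.append(p)
        else:
            scores.append(score_frame(fr, config, seq.topology, activity_score=activity))

    scored = [fs for fs in scores if fs.usable]
    if not scored:
        raise ReportError("no frames could be scored")
    frac = len(scored) / len(seq.frames)
    if frac < config.min_scored_fraction:
        raise ReportError(
            f"only {len(scored)}/{len(seq.frames)} frames scored "
            f"({frac:.0%} < {config.min_scored_fraction:.0%}); refusing to report a mean"
        )
    rebas = [fs.reba_result.reba for fs in scored]
    per_joint = {
        g: float(np.mean([getattr(fs.reba_result.sub_scores, g) for fs in scored]))
        for g in _JOINT_GROUPS
    }
    return ProcedureReport(
        subject_id=seq.subject_id,
        condition=seq.condition,
        n_frames_total=len(seq.frames),
        n_frames_scored=len(scored),
        mean_reba=float(np.mean(rebas)),
        per_joint_means=per_joint,
        frame_scores=scores,
        config_snapshot=config.snapshot(),
    )
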