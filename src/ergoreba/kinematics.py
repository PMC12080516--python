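"""Joint-angle extraction from 3D pose landmarks.

A :class:`PoseFrame` is reduced to the signed flexion angles and boolean
posture flags that REBA categorisation consumes. All geometry is expressed
in a per-frame anatomical triad derived from the subject's own hips
(``body_axes``), which makes every output invariant to rigid translation
and to rotation of the whole skeleton about the vertical.

Sign conventions
----------------
* Flexion is positive, extension negative, on a single axis per joint.
* Trunk flexion is the angle of the trunk vector's sagittal-plane
  projection from the vertical (+ forward lean); the lateral component is
  reported separately as side-bend, so flexion and side-bend decompose
  independently.
* Neck flexion is the sagittal angle of the neck vector minus that of the
  trunk vector (head-on-trunk, + forward).
* Upper-arm elevation is the full 3D angle between the upper arm and the
  downward trunk direction; elbow and knee flexion are 180 degrees minus
  the interior angle at the joint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .pose_model import PoseFrame

Vec = np.ndarray
UP = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """A joint group's landmarks coincide or are otherwise unusable."""


@dataclass(frozen=True)
class KinematicsConfig:
    """Detection thresholds (degrees / metres). Defaults are round values
    consistent with how the REBA worksheet is applied in practice; all are
    exposed so sensitivity can be studied."""

    twist_threshold_deg: float = 15.0
    side_bend_threshold_deg: float = 10.0
    abduction_threshold_deg: float = 20.0
    shoulder_raised_threshold_deg: float = 10.0
    support_ankle_gap_m: float = 0.10
    min_visibility: float = 0.5
    #: optional moving-average landmark smoothing window (frames); 0 = off.
    smoothing_window: int = 0


DEFAULT_KINEMATICS = KinematicsConfig()


@dataclass(frozen=True)
class JointAngles:
    """Kinematic summary of one frame: inputs to REBA categorisation."""

    neck_flexion_deg: float
    neck_twisted: bool
    neck_side_bent: bool
    trunk_flexion_deg: float
    trunk_twisted: bool
    trunk_side_bent: bool
    knee_flexion_deg_left: float
    knee_flexion_deg_right: float
    unilateral_support: bool
    upper_arm_elevation_deg_left: float
    upper_arm_elevation_deg_right: float
    shoulder_raised_left: bool
    shoulder_raised_right: bool
    arm_abducted_left: bool
    arm_abducted_right: bool
    arm_supported_left: bool
    arm_supported_right: bool
    elbow_flexion_deg_left: float
    elbow_flexion_deg_right: float
    wrist_flexion_deg_left: Optional[float] = None
    wrist_flexion_deg_right: Optional[float] = None
    wrist_deviated_or_twisted_left: Optional[bool] = None
    wrist_deviated_or_twisted_right: Optional[bool] = None

    def tracked(self) -> dict[str, float]:
        """Continuous angles used by temporal activity detection."""
        out = {
            "neck_flexion": self.neck_flexion_deg,
            "trunk_flexion": self.trunk_flexion_deg,
            "knee_left": self.knee_flexion_deg_left,
            "knee_right": self.knee_flexion_deg_right,
            "arm_left": self.upper_arm_elevation_deg_left,
            "arm_right": self.upper_arm_elevation_deg_right,
            "elbow_left": self.elbow_flexion_deg_left,
            "elbow_right": self.elbow_flexion_deg_right,
        }
        if self.wrist_flexion_deg_left is not None:
            out["wrist_left"] = self.wrist_flexion_deg_left
        if self.wrist_flexion_deg_right is not None:
            out["wrist_right"] = self.wrist_flexion_deg_right
        return out


def angle_between(u: Vec, v: Vec) -> float:
    """Unsigned angle between two 3-vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle_between: zero-length vector")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _pt(frame: PoseFrame, name: str) -> Vec:
    lm = frame.landmarks.get(name)
    if lm is None:
        raise DegenerateGeometryError(f"missing landmark {name!r}")
    return np.array(lm.xyz, dtype=float)


def _unit(v: Vec, what: str) -> Vec:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"degenerate geometry: {what}")
    return v / n


def body_axes(frame: PoseFrame) -> tuple[Vec, Vec, Vec]:
    """Anatomical (right, forward, up) orthonormal triad from the hips.

    right follows the hip line, up is the world vertical, forward completes
    the right-handed triad (up x right, re-orthogonalised).
    """
    hip_line = _pt(frame, "right_hip") - _pt(frame, "left_hip")
    forward = _unit(np.cross(UP, hip_line), "hip line parallel to vertical or hips coincident")
    right = np.cross(forward, UP)  # unit by construction
    return right, forward, UP.copy()


def _sagittal_angle(v: Vec, forward: Vec, up: Vec, what: str) -> float:
    """Angle of v's sagittal-plane projection from up, + toward forward."""
    f, u = float(np.dot(v, forward)), float(np.dot(v, up))
    if abs(f) < 1e-12 and abs(u) < 1e-12:
        raise DegenerateGeometryError(f"{what}: vector normal to sagittal plane")
    return math.degrees(math.atan2(f, u))


def _lateral_angle(v: Vec, right: Vec, what: str) -> float:
    """Out-of-sagittal-plane tilt of v, + toward the subject's right."""
    s = float(np.dot(_unit(v, what), right))
    return math.degrees(math.asin(max(-1.0, min(1.0, s))))


def _horizontal_angle(a: Vec, b: Vec, what: str) -> float:
    """Unsigned angle between the horizontal projections of two vectors."""
    ah = a - np.dot(a, UP) * UP
    bh = b - np.dot(b, UP) * UP
    if np.linalg.norm(ah) < 1e-12 or np.linalg.norm(bh) < 1e-12:
        raise DegenerateGeometryError(f"{what}: vertical line has no horizontal direction")
    return angle_between(ah, bh)


def _mid(frame: PoseFrame, left: str, right: str) -> Vec:
    return 0.5 * (_pt(frame, left) + _pt(frame, right))


def _trunk_vector(frame: PoseFrame) -> Vec:
    v = _mid(frame, "left_shoulder", "right_shoulder") - _mid(frame, "left_hip", "right_hip")
    return _unit(v, "trunk (shoulders coincide with hips)")


@dataclass(frozen=True)
class TrunkAngles:
    flexion_deg: float
    twisted: bool
    side_bent: bool


def trunk_angles(frame: PoseFrame, config: KinematicsConfig = DEFAULT_KINEMATICS) -> TrunkAngles:
    right, forward, up = body_axes(frame)
    t = _trunk_vector(frame)
    flexion = _sagittal_angle(t, forward, up, "trunk")
    side = _lateral_angle(t, right, "trunk")
    shoulder_line = _pt(frame, "right_shoulder") - _pt(frame, "left_shoulder")
    hip_line = _pt(frame, "right_hip") - _pt(frame, "left_hip")
    twist = _horizontal_angle(shoulder_line, hip_line, "trunk twist")
    return TrunkAngles(
        flexion_deg=flexion,
        twisted=twist > config.twist_threshold_deg,
        side_bent=abs(side) > config.side_bend_threshold_deg,
    )


@dataclass(frozen=True)
class NeckAngles:
    flexion_deg: float
    twisted: bool
    side_bent: bool


def _head_point(frame: PoseFrame, min_visibility: float) -> Vec:
    """Mid-ear, falling back to the nose when the ears are unreliable."""
    le, re = frame.get("left_ear"), frame.get("right_ear")
    if (
        le is not None and re is not None
        and le.visibility >= min_visibility and re.visibility >= min_visibility
    ):
        return _mid(frame, "left_ear", "right_ear")
    nose = frame.get("nose")
    if nose is not None and nose.visibility >= min_visibility:
        return np.array(nose.xyz, dtype=float)
    raise DegenerateGeometryError("neck: neither ears nor nose usable")


def neck_angles(frame: PoseFrame, config: KinematicsConfig = DEFAULT_KINEMATICS) -> NeckAngles:
    right, forward, up = body_axes(frame)
    t = _trunk_vector(frame)
    n = _head_point(frame, config.min_visibility) - _mid(frame, "left_shoulder", "right_shoulder")
    n = _unit(n, "neck (head coincides with shoulders)")
    flexion = _sagittal_angle(n, forward, up, "neck") - _sagittal_angle(t, forward, up, "trunk")
    side = _lateral_angle(n, right, "neck") - _lateral_angle(t, right, "trunk")
    shoulder_line = _pt(frame, "right_shoulder") - _pt(frame, "left_shoulder")
    try:
        ear_line = _pt(frame, "right_ear") - _pt(frame, "left_ear")
        twist_deg = _horizontal_angle(ear_line, shoulder_line, "neck twist")
    except DegenerateGeometryError:
        twist_deg = 0.0  # no ear line: rotation is undetectable, not flagged
    return NeckAngles(
        flexion_deg=flexion,
        twisted=twist_deg > config.twist_threshold_deg,
        side_bent=abs(side) > config.side_bend_threshold_deg,
    )


@dataclass(frozen=True)
class ArmAngles:
    upper_arm_elevation_deg: float
    shoulder_raised: bool
    abducted: bool
    supported: bool
    elbow_flexion_deg: float
    wrist_flexion_deg: Optional[float]
    wrist_deviated_or_twisted: Optional[bool]


def arm_angles(
    frame: PoseFrame,
    side: str,
    config: KinematicsConfig = DEFAULT_KINEMATICS,
) -> ArmAngles:
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    right, forward, up = body_axes(frame)
    down = -_trunk_vector(frame)
    shoulder = _pt(frame, f"{side}_shoulder")
    elbow = _pt(frame, f"{side}_elbow")
    wrist = _pt(frame, f"{side}_wrist")

    upper = elbow - shoulder
    elevation = angle_between(upper, down)
    abduction = abs(_lateral_angle(upper, right, f"{side} upper arm"))
    abducted = abduction > config.abduction_threshold_deg

    other = "right" if side == "left" else "left"
    d_y = float(_pt(frame, f"{side}_shoulder")[1] - _pt(frame, f"{other}_shoulder")[1])
    line_len = float(np.linalg.norm(_pt(frame, f"{side}_shoulder") - _pt(frame, f"{other}_shoulder")))
    if line_len < 1e-12:
        raise DegenerateGeometryError("shoulders coincident")
    tilt = math.degrees(math.asin(max(-1.0, min(1.0, d_y / line_len))))
    shoulder_raised = tilt > config.shoulder_raised_threshold_deg

    forearm = wrist - elbow
    elbow_flexion = 180.0 - angle_between(-upper, forearm)

    wrist_flexion: Optional[float] = None
    wrist_flag: Optional[bool] = None
    index = frame.get(f"{side}_index")
    if index is not None and index.visibility >= config.min_visibility:
        hand = np.array(index.xyz) - wrist
        if np.linalg.norm(hand) > 1e-12 and np.linalg.norm(forearm) > 1e-12:
            mag = angle_between(hand, forearm)
            # sign: + when the hand tips toward the subject's forward
            perp = hand / np.linalg.norm(hand) - math.cos(math.radians(mag)) * forearm / np.linalg.norm(forearm)
            sign = 1.0 if float(np.dot(perp, forward)) >= 0 else -1.0
            wrist_flexion = sign * mag
            wrist_flag = False  # deviation/twist needs full hand pose; not flagged here

    return ArmAngles(
        upper_arm_elevation_deg=elevation,
        shoulder_raised=shoulder_raised,
        abducted=abducted,
        supported=False,  # not geometrically observable; pipeline config may override
        elbow_flexion_deg=elbow_flexion,
        wrist_flexion_deg=wrist_flexion,
        wrist_deviated_or_twisted=wrist_flag,
    )


@dataclass(frozen=True)
class LegAngles:
    knee_flexion_deg_left: float
    knee_flexion_deg_right: float
    unilateral_support: bool


def leg_angles(frame: PoseFrame, config: KinematicsConfig = DEFAULT_KINEMATICS) -> LegAngles:
    def knee_flexion(side: str) -> float:
        hip = _pt(frame, f"{side}_hip")
        knee = _pt(frame, f"{side}_knee")
        ankle = _pt(frame, f"{side}_ankle")
        return 180.0 - angle_between(hip - knee, ankle - knee)

    left = knee_flexion("left")
    right = knee_flexion("right")
    gap = abs(float(_pt(frame, "left_ankle")[1] - _pt(frame, "right_ankle")[1]))
    return LegAngles(
        knee_flexion_deg_left=left,
        knee_flexion_deg_right=right,
        unilateral_support=gap > config.support_ankle_gap_m,
    )


def compute_joint_angles(
    frame: PoseFrame,
    config: KinematicsConfig = DEFAULT_KINEMATICS,
) -> JointAngles:
    """Assemble the full kinematic summary of one frame.

    Deterministic for fixed input and config. Degenerate-geometry errors
    from sub-computations name the joint group that failed.
    """
    trunk = trunk_angles(frame, config)
    neck = neck_angles(frame, config)
    legs = leg_angles(frame, config)
    left = arm_angles(frame, "left", config)
    right = arm_angles(frame, "right", config)
    return JointAngles(
        neck_flexion_deg=neck.flexion_deg,
        neck_twisted=neck.twisted,
        neck_side_bent=neck.side_bent,
        trunk_flexion_deg=trunk.flexion_deg,
        trunk_twisted=trunk.twisted,
        trunk_side_bent=trunk.side_bent,
        knee_flexion_deg_left=legs.knee_flexion_deg_left,
        knee_flexion_deg_right=legs.knee_flexion_deg_right,
        unilateral_support=legs.unilateral_support,
        upper_arm_elevation_deg_left=left.upper_arm_elevation_deg,
        upper_arm_elevation_deg_right=right.upper_arm_elevation_deg,
        shoulder_raised_left=left.shoulder_raised,
        shoulder_raised_right=right.shoulder_raised,
        arm_abducted_left=left.abducted,
        arm_abducted_right=right.abducted,
        arm_supported_left=left.supported,
        arm_supported_right=right.supported,
        elbow_flexion_deg_left=left.elbow_flexion_deg,
        elbow_flexion_deg_right=right.elbow_flexion_deg,
        wrist_flexion_deg_left=left.wrist_flexion_deg,
        wrist_flexion_deg_right=right.wrist_flexion_deg,
        wrist_deviated_or_twisted_left=left.wrist_deviated_or_twisted,
        wrist_deviated_or_twisted_right=right.wrist_deviated_or_twisted,
    )
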