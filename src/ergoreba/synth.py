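"""Synthetic posed skeletons and scenario sequences with known ground truth.

The generator builds a proportioned 33-landmark skeleton (segment lengths
as fixed fractions of stature, from standard anthropometric proportion
tables) and applies specified rotations using exactly the angle definitions
the kinematics module measures, so that noise-free recovery is exact up to
floating-point error. It emulates the two bed-height conditions of the
endoscopy bed-position study — an optimal bed (5-10 cm below elbow height,
near-neutral postures) and a low bed (slightly above knee height, crouched
and contorted postures). The posture distributions themselves are synthetic:
they claim directional, not quantitative, fidelity to real endoscopists.

All randomness derives from one integer seed via per-frame SeedSequence
spawn keys, so any subsequence is reproducible independently of draw order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .pose_model import Landmark, LandmarkSequence, PoseFrame
from .topology import BLAZEPOSE

# Segment lengths as fractions of stature (Drillis & Contini style tables).
_FR = {
    "hip_height": 0.530,       # ground to hip joint
    "trunk": 0.288,            # hip to shoulder
    "neck": 0.118,             # shoulder line to ear level
    "shoulder_halfwidth": 0.129,
    "hip_halfwidth": 0.0955,
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "thigh": 0.245,
    "shank": 0.246,
    "head_radius": 0.065,
    "foot": 0.152,
}


@dataclass(frozen=True)
class PostureSpec:
    """Ground-truth posture parameters for one generated frame.

    Angles in degrees, following the kinematics sign conventions; heights
    in centimetres; distances in metres.
    """

    subject_height_cm: float = 175.0
    trunk_flexion_deg: float = 0.0
    trunk_twist_deg: float = 0.0
    trunk_side_bend_deg: float = 0.0
    neck_flexion_deg: float = 0.0
    neck_twist_deg: float = 0.0
    arm_elevation_deg_left: float = 0.0
    arm_elevation_deg_right: float = 0.0
    arm_abducted_left: bool = False
    arm_abducted_right: bool = False
    elbow_flexion_deg_left: float = 0.0
    elbow_flexion_deg_right: float = 0.0
    wrist_flexion_deg_left: float = 0.0
    wrist_flexion_deg_right: float = 0.0
    knee_flexion_deg_left: float = 0.0
    knee_flexion_deg_right: float = 0.0
    stance_width_m: float = 0.25
    shoulder_tilt_deg: float = 0.0   # + = right shoulder higher
    raised_ankle_m: float = 0.0      # + = left ankle lifted

    _RANGES = {
        "trunk_flexion_deg": (-30.0, 110.0),
        "trunk_twist_deg": (-60.0, 60.0),
        "trunk_side_bend_deg": (-40.0, 40.0),
        "neck_flexion_deg": (-40.0, 60.0),
        "neck_twist_deg": (-70.0, 70.0),
        "arm_elevation_deg_left": (0.0, 170.0),
        "arm_elevation_deg_right": (0.0, 170.0),
        "elbow_flexion_deg_left": (0.0, 150.0),
        "elbow_flexion_deg_right": (0.0, 150.0),
        "wrist_flexion_deg_left": (-80.0, 80.0),
        "wrist_flexion_deg_right": (-80.0, 80.0),
        "knee_flexion_deg_left": (0.0, 150.0),
        "knee_flexion_deg_right": (0.0, 150.0),
        "shoulder_tilt_deg": (-30.0, 30.0),
    }

    def __post_init__(self) -> None:
        if not (140.0 <= self.subject_height_cm <= 210.0):
            raise ValueError(
                f"subject_height_cm {self.subject_height_cm} outside [140, 210]"
            )
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside anatomical range [{lo}, {hi}]")

    def mirrored(self) -> "PostureSpec":
        return replace(
            self,
            trunk_twist_deg=-self.trunk_twist_deg,
            trunk_side_bend_deg=-self.trunk_side_bend_deg,
            neck_twist_deg=-self.neck_twist_deg,
            arm_elevation_deg_left=self.arm_elevation_deg_right,
            arm_elevation_deg_right=self.arm_elevation_deg_left,
            arm_abducted_left=self.arm_abducted_right,
            arm_abducted_right=self.arm_abducted_left,
            elbow_flexion_deg_left=self.elbow_flexion_deg_right,
            elbow_flexion_deg_right=self.elbow_flexion_deg_left,
            wrist_flexion_deg_left=self.wrist_flexion_deg_right,
            wrist_flexion_deg_right=self.wrist_flexion_deg_left,
            knee_flexion_deg_left=self.knee_flexion_deg_right,
            knee_flexion_deg_right=self.knee_flexion_deg_left,
            shoulder_tilt_deg=-self.shoulder_tilt_deg,
            raised_ankle_m=-self.raised_ankle_m,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str          # "optimal_bed" | "low_bed"
    n_frames: int = 120
    fps: float = 1.0
    noise_sd_m: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("optimal_bed", "low_bed"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be nonnegative")


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = math.radians(deg)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_posed_skeleton(
    spec: PostureSpec,
    frame_index: int = 0,
    timestamp_s: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    noise_sd_m: float = 0.0,
) -> PoseFrame:
    """Build one 33-landmark frame realising the specified posture.

    The subject faces +Z with hips on the X axis (subject's right at -X),
    mid-hip at the origin, gravity along -Y. Optional isotropic Gaussian
    jitter of ``noise_sd_m`` is added to every landmark.
    """
    h = spec.subject_height_cm / 100.0
    right = np.array([-1.0, 0.0, 0.0])   # subject's right
    forward = np.array([0.0, 0.0, 1.0])
    up = np.array([0.0, 1.0, 0.0])

    def dir_from_angles(sagittal_deg: float, lateral_deg: float) -> np.ndarray:
        """Unit vector with given sagittal-projection and lateral angles."""
        sa, la = math.radians(sagittal_deg), math.radians(lateral_deg)
        return (
            math.sin(la) * right
            + math.cos(la) * math.cos(sa) * up
            + math.cos(la) * math.sin(sa) * forward
        )

    pts: dict[str, np.ndarray] = {}
    mid_hip = np.zeros(3)
    hip_hw = _FR["hip_halfwidth"] * h
    pts["left_hip"] = mid_hip - hip_hw * right
    pts["right_hip"] = mid_hip + hip_hw * right

    # trunk and shoulder girdle
    t_dir = dir_from_angles(spec.trunk_flexion_deg, spec.trunk_side_bend_deg)
    mid_sh = mid_hip + _FR["trunk"] * h * t_dir
    sh_line = _rot(up, -spec.trunk_twist_deg) @ right  # yaw; -deg = leading right shoulder forward
    sh_hw = _FR["shoulder_halfwidth"] * h
    tilt = math.radians(spec.shoulder_tilt_deg)
    pts["left_shoulder"] = mid_sh - sh_hw * sh_line - sh_hw * math.tan(tilt) * up
    pts["right_shoulder"] = mid_sh + sh_hw * sh_line + sh_hw * math.tan(tilt) * up
    mid_sh = 0.5 * (pts["left_shoulder"] + pts["right_shoulder"])

    # head: neck flexion is head-on-trunk in the sagittal plane
    n_dir = dir_from_angles(
        spec.trunk_flexion_deg + spec.neck_flexion_deg, spec.trunk_side_bend_deg
    )
    mid_ear = mid_sh + _FR["neck"] * h * n_dir
    ear_line = _rot(up, -(spec.trunk_twist_deg + spec.neck_twist_deg)) @ right
    hr = _FR["head_radius"] * h
    pts["left_ear"] = mid_ear - hr * ear_line
    pts["right_ear"] = mid_ear + hr * ear_line
    head_fwd = np.cross(up, ear_line)
    head_fwd = head_fwd / np.linalg.norm(head_fwd)
    pts["nose"] = mid_ear + hr * head_fwd
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        pts[f"{side}_eye"] = mid_ear + 0.8 * hr * head_fwd + 0.4 * hr * sgn * ear_line + 0.3 * hr * up
        pts[f"{side}_eye_inner"] = pts[f"{side}_eye"] - 0.15 * hr * sgn * ear_line
        pts[f"{side}_eye_outer"] = pts[f"{side}_eye"] + 0.15 * hr * sgn * ear_line
        pts[f"mouth_{side}"] = mid_ear + 0.9 * hr * head_fwd + 0.3 * hr * sgn * ear_line - 0.3 * hr * up

    # arms
    down = -t_dir
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        shoulder = pts[f"{side}_shoulder"]
        elev = getattr(spec, f"arm_elevation_deg_{side}")
        abducted = getattr(spec, f"arm_abducted_{side}")
        plane_dir = sgn * right if abducted else forward
        p = plane_dir - np.dot(plane_dir, down) * down
        p = p / np.linalg.norm(p)
        e = math.radians(elev)
        u_arm = math.cos(e) * down + math.sin(e) * p
        elbow = shoulder + _FR["upper_arm"] * h * u_arm
        pts[f"{side}_elbow"] = elbow

        ef = math.radians(getattr(spec, f"elbow_flexion_deg_{side}"))
        b = forward - np.dot(forward, u_arm) * u_arm
        if np.linalg.norm(b) < 1e-6:
            b = up - np.dot(up, u_arm) * u_arm
        b = b / np.linalg.norm(b)
        f_arm = math.cos(ef) * u_arm + math.sin(ef) * b
        wrist = elbow + _FR["forearm"] * h * f_arm
        pts[f"{side}_wrist"] = wrist

        wf = math.radians(getattr(spec, f"wrist_flexion_deg_{side}"))
        b2 = forward - np.dot(forward, f_arm) * f_arm
        if np.linalg.norm(b2) < 1e-6:
            b2 = up - np.dot(up, f_arm) * f_arm
        b2 = b2 / np.linalg.norm(b2)
        hand_dir = math.cos(wf) * f_arm + math.sin(wf) * b2
        hand_len = _FR["hand"] * h
        pts[f"{side}_index"] = wrist + hand_len * hand_dir
        lat = np.cross(f_arm, b2)
        pts[f"{side}_pinky"] = wrist + 0.9 * hand_len * hand_dir + 0.2 * hand_len * sgn * lat
        pts[f"{side}_thumb"] = wrist + 0.5 * hand_len * hand_dir - 0.2 * hand_len * sgn * lat

    # legs: thighs hang vertically, shank rotates forward by knee flexion
    stance = 0.5 * spec.stance_width_m
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        hip = pts[f"{side}_hip"]
        thigh_dir = _FR["thigh"] * h * (-up) + (stance - hip_hw) * sgn * right
        thigh_dir = thigh_dir / np.linalg.norm(thigh_dir)
        knee = hip + _FR["thigh"] * h * thigh_dir
        pts[f"{side}_knee"] = knee
        kf = math.radians(getattr(spec, f"knee_flexion_deg_{side}"))
        bend = forward - np.dot(forward, thigh_dir) * thigh_dir
        bend = bend / np.linalg.norm(bend)
        shank_dir = math.cos(kf) * thigh_dir + math.sin(kf) * bend
        ankle = knee + _FR["shank"] * h * shank_dir
        if side == "left":
            ankle = ankle + max(0.0, spec.raised_ankle_m) * up
        else:
            ankle = ankle + max(0.0, -spec.raised_ankle_m) * up
        pts[f"{side}_ankle"] = ankle
        pts[f"{side}_heel"] = ankle - 0.3 * _FR["foot"] * h * forward
        pts[f"{side}_foot_index"] = ankle + 0.7 * _FR["foot"] * h * forward - 0.05 * h * up

    if noise_sd_m > 0:
        if rng is None:
            raise ValueError("noise requested but no rng supplied")
        for name in pts:
            pts[name] = pts[name] + rng.normal(0.0, noise_sd_m, size=3)

    landmarks = {
        name: Landmark(name, float(p[0]), float(p[1]), float(p[2]), 1.0)
        for name, p in pts.items()
        if name in BLAZEPOSE.names
    }
    return PoseFrame(frame_index=frame_index, timestamp_s=timestamp_s, landmarks=landmarks)


def _frame_rng(seed: int, stream: int, frame: int) -> np.random.Generator:
    """Independent generator for one (stream, frame) pair of one seed."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(seed, spawn_key=(stream, frame)))
    )


def _draw_optimal(rng: np.random.Generator, height_cm: float) -> PostureSpec:
    """Near-neutral working posture at a well-positioned bed."""
    return PostureSpec(
        subject_height_cm=height_cm,
        trunk_flexion_deg=rng.uniform(0.0, 10.0),
        neck_flexion_deg=rng.uniform(0.0, 15.0),
        arm_elevation_deg_left=rng.uniform(0.0, 15.0),
        arm_elevation_deg_right=rng.uniform(0.0, 15.0),
        elbow_flexion_deg_left=rng.uniform(60.0, 100.0),
        elbow_flexion_deg_right=rng.uniform(60.0, 100.0),
        wrist_flexion_deg_left=rng.uniform(-10.0, 10.0),
        wrist_flexion_deg_right=rng.uniform(-10.0, 10.0),
        knee_flexion_deg_left=rng.uniform(0.0, 10.0),
        knee_flexion_deg_right=rng.uniform(0.0, 10.0),
    )


def _draw_low(rng: np.random.Generator, height_cm: float) -> PostureSpec:
    """Crouched, twisted posture reaching down to a low bed."""
    knee = rng.uniform(20.0, 60.0)
    return PostureSpec(
        subject_height_cm=height_cm,
        trunk_flexion_deg=rng.uniform(25.0, 60.0),
        trunk_twist_deg=rng.uniform(15.0, 35.0) * rng.choice([-1.0, 1.0]),
        neck_flexion_deg=rng.uniform(15.0, 35.0),
        arm_elevation_deg_left=rng.uniform(30.0, 70.0),
        arm_elevation_deg_right=rng.uniform(30.0, 70.0),
        elbow_flexion_deg_left=rng.uniform(30.0, 130.0),
        elbow_flexion_deg_right=rng.uniform(30.0, 130.0),
        wrist_flexion_deg_left=rng.uniform(-30.0, 30.0),
        wrist_flexion_deg_right=rng.uniform(-30.0, 30.0),
        knee_flexion_deg_left=knee + rng.uniform(-5.0, 5.0),
        knee_flexion_deg_right=knee + rng.uniform(-5.0, 5.0),
    )


def make_scenario_sequence(
    config: ScenarioConfig,
    subject_height_cm: float = 175.0,
    subject_id: str = "",
) -> LandmarkSequence:
    """Generate a seeded landmark sequence for one bed-height condition."""
    draw = _draw_optimal if config.scenario == "optimal_bed" else _draw_low
    frames = []
    for i in range(config.n_frames):
        rng = _frame_rng(config.seed, 0, i)
        spec = draw(rng, subject_height_cm)
        frames.append(
            make_posed_skeleton(
                spec,
                frame_index=i,
                timestamp_s=i / config.fps,
                rng=rng if config.noise_sd_m > 0 else None,
                noise_sd_m=config.noise_sd_m,
            )
        )
    return LandmarkSequence(
        frames=frames,
        fps=config.fps,
        subject_id=subject_id,
        condition=config.scenario,
    )


def random_posture_spec(
    rng: np.random.Generator,
    height_cm: float | None = None,
    max_angle_deg: float = 90.0,
) -> PostureSpec:
    """A random posture spanning the whole scorable range; used as ground
    truth in kinematic round-trip tests and internal-agreement checks."""
    if height_cm is None:
        height_cm = rng.uniform(160.0, 193.0)
    m = max_angle_deg
    return PostureSpec(
        subject_height_cm=height_cm,
        trunk_flexion_deg=rng.uniform(0.0, m),
        trunk_twist_deg=rng.uniform(-min(m, 45.0), min(m, 45.0)),
        trunk_side_bend_deg=rng.uniform(-min(m, 25.0), min(m, 25.0)),
        neck_flexion_deg=rng.uniform(0.0, min(m, 50.0)),
        neck_twist_deg=rng.uniform(-min(m, 60.0), min(m, 60.0)),
        arm_elevation_deg_left=rng.uniform(0.0, m),
        arm_elevation_deg_right=rng.uniform(0.0, m),
        elbow_flexion_deg_left=rng.uniform(0.0, m),
        elbow_flexion_deg_right=rng.uniform(0.0, m),
        wrist_flexion_deg_left=rng.uniform(0.0, min(m, 45.0)),
        wrist_flexion_deg_right=rng.uniform(0.0, min(m, 45.0)),
        knee_flexion_deg_left=rng.uniform(0.0, m),
        knee_flexion_deg_right=rng.uniform(0.0, m),
    )


def make_validation_frames(n: int = 10, seed: int = 42) -> list[PoseFrame]:
    """Distinct noise-free postures of graded severity for repeatability
    studies: item scores span the REBA range so rank correlations between
    repeated scorings are well defined."""
    frames = []
    for i in range(n):
        rng = _frame_rng(seed, 1, i)
        severity = i / max(n - 1, 1)
        spec = PostureSpec(
            subject_height_cm=rng.uniform(160.0, 193.0),
            trunk_flexion_deg=severity * 70.0,
            trunk_twist_deg=severity * 30.0,
            neck_flexion_deg=severity * 30.0,
            arm_elevation_deg_left=severity * 100.0,
            arm_elevation_deg_right=severity * 100.0,
            elbow_flexion_deg_left=80.0 + severity * 50.0,
            elbow_flexion_deg_right=80.0 + severity * 50.0,
            wrist_flexion_deg_left=severity * 25.0,
            wrist_flexion_deg_right=severity * 25.0,
            knee_flexion_deg_left=severity * 70.0,
            knee_flexion_deg_right=severity * 70.0,
        )
        frames.append(make_posed_skeleton(spec, frame_index=i, timestamp_s=float(i)))
    return frames


def load_table2_fixture() -> pd.DataFrame:
    """The bed-height study's printed per-subject results: mean REBA per
    endoscopist at optimal and low bed height, with subject metadata."""
    ref = resources.files("ergoreba.data").joinpath("bed_height_study.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def study_heights_cm() -> list[float]:
    """The ten study subjects' statures (160-193 cm)."""
    return [float(h) for h in load_table2_fixture()["height_cm"]]
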