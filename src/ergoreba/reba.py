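"""REBA (Rapid Entire Body Assessment) scoring.

Joint angles are categorised into integer posture sub-scores, combined
through the worksheet's Tables A/B/C with load, coupling and activity
adjustments, and mapped to a final 1-15 score and action-level risk band.

The three lookup tables are shipped as CSV data files transcribed verbatim
from the published REBA worksheet (Hignett & McAtamney, Appl Ergon 2000)
and verified by SHA-256 checksum on load; sub-scores are clamped into the
printed table domains because worksheet adjustments (twist, side-bend,
abduction, raised shoulder) can push a category past its table axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .kinematics import JointAngles

_TABLE_SHA256 = {
    "reba_table_a.csv": "b966a9756f8af0277c0b126e8f1327a6ba19856afc7f2b9e94803a72bca33be9",
    "reba_table_b.csv": "36e8de2653a6741b8ecfe9efb35b0a8b44e8898d4aa781565c1bf3e2e26e7883",
    "reba_table_c.csv": "c4bb5ce4a3dfa9289af896cb9627a24a78834245f5c2e05766fd42c24144c1d5",
}

RISK_BANDS = (
    (1, 1, "negligible"),
    (2, 3, "low"),
    (4, 7, "medium"),
    (8, 10, "high"),
    (11, 15, "very_high"),
)


class ScoringError(ValueError):
    """A frame cannot be scored (missing fields or out-of-domain lookup)."""


def _load_table(filename: str, axes: tuple[str, ...]) -> np.ndarray:
    ref = resources.files("ergoreba.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256[filename]:
        raise RuntimeError(
            f"{filename}: checksum mismatch ({digest}); table data corrupted"
        )
    df = pd.read_csv(ref)
    shape = tuple(int(df[a].max()) for a in axes)
    arr = np.zeros(shape, dtype=int)
    for _, row in df.iterrows():
        idx = tuple(int(row[a]) - 1 for a in axes)
        arr[idx] = int(row["score"])
    return arr


_TABLE_A = _load_table("reba_table_a.csv", ("neck", "trunk", "legs"))
_TABLE_B = _load_table("reba_table_b.csv", ("upper_arm", "lower_arm", "wrist"))
_TABLE_C = _load_table("reba_table_c.csv", ("score_a", "score_b"))


def table_a(neck: int, trunk: int, legs: int) -> int:
    """Trunk/neck/legs combination score, 1-9."""
    if not (1 <= neck <= 3 and 1 <= trunk <= 5 and 1 <= legs <= 4):
        raise ScoringError(f"table_a argument out of domain: {(neck, trunk, legs)}")
    return int(_TABLE_A[neck - 1, trunk - 1, legs - 1])


def table_b(upper_arm: int, lower_arm: int, wrist: int) -> int:
    """Arm/wrist combination score, 1-9."""
    if not (1 <= upper_arm <= 6 and 1 <= lower_arm <= 2 and 1 <= wrist <= 3):
        raise ScoringError(
            f"table_b argument out of domain: {(upper_arm, lower_arm, wrist)}"
        )
    return int(_TABLE_B[upper_arm - 1, lower_arm - 1, wrist - 1])


def table_c(score_a: int, score_b: int) -> int:
    """Combined score, 1-12."""
    if not (1 <= score_a <= 12 and 1 <= score_b <= 12):
        raise ScoringError(f"table_c argument out of domain: {(score_a, score_b)}")
    return int(_TABLE_C[score_a - 1, score_b - 1])


def risk_band(reba: int) -> str:
    for lo, hi, band in RISK_BANDS:
        if lo <= reba <= hi:
            return band
    raise ScoringError(f"REBA score {reba} outside [1, 15]")


@dataclass(frozen=True)
class ScoringConfig:
    """Endoscopy-suite defaults: a scope weighs well under 5 kg (load 0)
    and has a good handle grip (coupling 0); arm support and the default
    wrist score cover body-only topologies without hand landmarks."""

    upright_trunk_tolerance_deg: float = 5.0
    default_wrist_score: int = 1
    arm_supported_override: bool | None = None


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class RebaAdjustments:
    """Load (force), coupling (grip quality) and activity adjustments."""

    load_score: int = 0
    coupling_score: int = 0
    activity_score: int = 0

    def __post_init__(self) -> None:
        for name in ("load_score", "coupling_score", "activity_score"):
            v = getattr(self, name)
            if not (0 <= v <= 3):
                raise ValueError(f"{name} must be in [0, 3], got {v}")


@dataclass(frozen=True)
class RebaSubScores:
    neck: int
    trunk: int
    legs: int
    upper_arm_left: int
    upper_arm_right: int
    lower_arm_left: int
    lower_arm_right: int
    wrist_left: int
    wrist_right: int


@dataclass(frozen=True)
class RebaResult:
    sub_scores: RebaSubScores
    adjustments: RebaAdjustments
    score_a: int
    score_b_left: int
    score_b_right: int
    scored_side: str
    score_c: int
    reba: int
    risk_band: str


def _clamp(v: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, v))


def neck_category(angles: JointAngles) -> int:
    """Worksheet neck step: 1 for 0-20 deg flexion, 2 beyond or in
    extension; +1 each for twist and side-bend; capped at the table axis."""
    f = angles.neck_flexion_deg
    base = 1 if 0.0 <= f <= 20.0 else 2
    score = base + int(angles.neck_twisted) + int(angles.neck_side_bent)
    return _clamp(score, 1, 3)


def trunk_category(
    angles: JointAngles, config: ScoringConfig = DEFAULT_SCORING
) -> int:
    f = angles.trunk_flexion_deg
    a = abs(f)
    tol = config.upright_trunk_tolerance_deg
    if a <= tol:
        base = 1
    elif a <= 20.0:
        base = 2
    elif f > 60.0:
        base = 4
    else:
        # flexion 20-60 or any extension beyond 20
        base = 3
    score = base + int(angles.trunk_twisted) + int(angles.trunk_side_bent)
    return _clamp(score, 1, 5)


def legs_category(angles: JointAngles) -> int:
    base = 2 if angles.unilateral_support else 1
    knee = max(angles.knee_flexion_deg_left, angles.knee_flexion_deg_right)
    if knee > 60.0:
        base += 2
    elif knee > 30.0:
        base += 1
    return _clamp(base, 1, 4)


def upper_arm_category(
    angles: JointAngles, side: str, config: ScoringConfig = DEFAULT_SCORING
) -> int:
    e = getattr(angles, f"upper_arm_elevation_deg_{side}")
    if e <= 20.0:
        base = 1
    elif e <= 45.0:
        base = 2
    elif e <= 90.0:
        base = 3
    else:
        base = 4
    score = base
    score += int(getattr(angles, f"arm_abducted_{side}"))
    score += int(getattr(angles, f"shoulder_raised_{side}"))
    supported = getattr(angles, f"arm_supported_{side}")
    if config.arm_supported_override is not None:
        supported = config.arm_supported_override
    if supported:
        score -= 1
    return _clamp(score, 1, 6)


def lower_arm_category(angles: JointAngles, side: str) -> int:
    f = getattr(angles, f"elbow_flexion_deg_{side}")
    return 1 if 60.0 <= f <= 100.0 else 2


def wrist_category(
    angles: JointAngles, side: str, config: ScoringConfig = DEFAULT_SCORING
) -> int:
    f = getattr(angles, f"wrist_flexion_deg_{side}")
    if f is None:
        return _clamp(config.default_wrist_score, 1, 3)
    score = 1 if abs(f) <= 15.0 else 2
    deviated = getattr(angles, f"wrist_deviated_or_twisted_{side}")
    if deviated:
        score += 1
    return _clamp(score, 1, 3)


def compute_reba(
    angles: JointAngles,
    adjustments: RebaAdjustments = RebaAdjustments(),
    config: ScoringConfig = DEFAULT_SCORING,
) -> RebaResult:
    """Full worksheet evaluation of one frame's joint angles.

    Score A = Table A(neck, trunk, legs) + load; Score B = Table B(upper
    arm, lower arm, wrist) + coupling, computed per arm with the worse
    (higher) side scored, ties to the right; REBA = Table C(A, B) +
    activity, in [1, 15].
    """
    sub = RebaSubScores(
        neck=neck_category(angles),
        trunk=trunk_category(angles, config),
        legs=legs_category(angles),
        upper_arm_left=upper_arm_category(angles, "left", config),
        upper_arm_right=upper_arm_category(angles, "right", config),
        lower_arm_left=lower_arm_category(angles, "left"),
        lower_arm_right=lower_arm_category(angles, "right"),
        wrist_left=wrist_category(angles, "left", config),
        wrist_right=wrist_category(angles, "right", config),
    )
    score_a = _clamp(
        table_a(sub.neck, sub.trunk, sub.legs) + adjustments.load_score, 1, 12
    )
    b_left = _clamp(
        table_b(sub.upper_arm_left, sub.lower_arm_left, sub.wrist_left)
        + adjustments.coupling_score, 1, 12,
    )
    b_right = _clamp(
        table_b(sub.upper_arm_right, sub.lower_arm_right, sub.wrist_right)
        + adjustments.coupling_score, 1, 12,
    )
    scored_side = "right" if b_right >= b_left else "left"
    score_b = b_right if scored_side == "right" else b_left
    score_c = table_c(score_a, score_b)
    reba = _clamp(score_c + adjustments.activity_score, 1, 15)
    return RebaResult(
        sub_scores=sub,
        adjustments=adjustments,
        score_a=score_a,
        score_b_left=b_left,
        score_b_right=b_right,
        scored_side=scored_side,
        score_c=score_c,
        reba=reba,
        risk_band=risk_band(reba),
    )
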