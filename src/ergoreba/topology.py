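"""Landmark naming conventions.

The canonical topology is the 33-landmark full-body convention popularised
by the BlazePose family of pose estimators. Scoring only requires a core
subset (head, shoulders, arms, hips, legs); the remaining face/hand/foot
points are carried through but never mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field


BLAZEPOSE_33 = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

#: Landmarks a frame must carry (with sufficient visibility) to be scorable.
REQUIRED_CORE = (
    "nose", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)


@dataclass(frozen=True)
class Topology:
    """A named landmark convention: the full name set plus the scoring core."""

    name: str
    names: tuple[str, ...]
    required_core: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(self.required_core) - set(self.names)
        if missing:
            raise ValueError(
                f"required_core not a subset of names: {sorted(missing)}"
            )


BLAZEPOSE = Topology("blazepose_33", BLAZEPOSE_33, REQUIRED_CORE)

_REGISTRY: dict[str, Topology] = {BLAZEPOSE.name: BLAZEPOSE}


def get_topology(name: str) -> Topology:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown topology {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def register_topology(topology: Topology) -> None:
    """Register an alternative convention (must map the core names)."""
    _REGISTRY[topology.name] = topology
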