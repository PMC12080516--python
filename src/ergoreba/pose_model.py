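"""Landmark data model and file I/O.

Coordinate convention: right-handed world frame in metres, +Y opposing
gravity, origin at the subject's mid-hip (per frame). A gravity-aligned
frame is required because REBA posture categories reference the vertical;
pose-backend adapters are responsible for converting estimator-native
coordinates into this frame.

Two on-disk formats are supported:

* JSON: ``{topology, fps, subject_id, condition, frames: [{frame_index,
  timestamp_s, landmarks: {name: {x, y, z, visibility}}}]}``.
* CSV: columns ``frame_index, timestamp_s, landmark, x, y, z, visibility``
  with a mandatory header row; sequence metadata is stored in ``#key=value``
  comment lines preceding the header.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .topology import BLAZEPOSE, Topology, get_topology

DEFAULT_MIN_VISIBILITY = 0.5
DEFAULT_MAX_FPS = 60.0


class LandmarkFileError(ValueError):
    """Malformed landmark file (parse- or invariant-level)."""


@dataclass(frozen=True)
class Landmark:
    """One named anatomical keypoint with a visibility confidence."""

    name: str
    x: float
    y: float
    z: float
    visibility: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.visibility <= 1.0):
            raise ValueError(
                f"{self.name}: visibility {self.visibility} outside [0, 1]"
            )
        for axis in ("x", "y", "z"):
            if not math.isfinite(getattr(self, axis)):
                raise ValueError(f"{self.name}: non-finite coordinate {axis}")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class PoseFrame:
    """All landmarks observed in one video frame."""

    frame_index: int
    timestamp_s: float
    landmarks: dict[str, Landmark]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"negative frame_index {self.frame_index}")
        if self.timestamp_s < 0:
            raise ValueError(f"negative timestamp {self.timestamp_s}")
        for name, lm in self.landmarks.items():
            if name != lm.name:
                raise ValueError(f"landmark keyed {name!r} but named {lm.name!r}")

    def get(self, name: str) -> Landmark | None:
        return self.landmarks.get(name)


@dataclass(frozen=True)
class ValidationResult:
    usable: bool
    missing: tuple[str, ...]


def validate_frame(
    frame: PoseFrame,
    topology: Topology = BLAZEPOSE,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
) -> ValidationResult:
    """Report whether a frame is scorable.

    A frame is usable iff every ``required_core`` landmark is present with
    visibility >= ``min_visibility``. Never raises; missing names are
    reported so callers can log dropped frames.
    """
    if not (0.0 <= min_visibility <= 1.0):
        raise ValueError("min_visibility must lie in [0, 1]")
    missing = tuple(
        name
        for name in topology.required_core
        if (lm := frame.landmarks.get(name)) is None
        or lm.visibility < min_visibility
    )
    return ValidationResult(usable=not missing, missing=missing)


@dataclass
class LandmarkSequence:
    """An ordered landmark recording of one subject in one condition."""

    frames: list[PoseFrame]
    fps: float
    topology: str = BLAZEPOSE.name
    subject_id: str = ""
    condition: str = ""
    max_fps: float = DEFAULT_MAX_FPS

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.fps > self.max_fps:
            raise ValueError(
                f"fps {self.fps} exceeds the maximum processing rate "
                f"{self.max_fps}; downsample first"
            )
        topo = get_topology(self.topology)
        valid_names = set(topo.names)
        self.frames = sorted(self.frames, key=lambda f: f.frame_index)
        seen: set[int] = set()
        prev_t = -math.inf
        for fr in self.frames:
            if fr.frame_index in seen:
                raise ValueError(f"duplicate frame_index {fr.frame_index}")
            seen.add(fr.frame_index)
            if fr.timestamp_s < prev_t:
                raise ValueError(
                    f"timestamp decreases at frame {fr.frame_index} "
                    f"({fr.timestamp_s} < {prev_t})"
                )
            prev_t = fr.timestamp_s
            unknown = set(fr.landmarks) - valid_names
            if unknown:
                raise ValueError(
                    f"frame {fr.frame_index}: unknown landmark names "
                    f"{sorted(unknown)} for topology {self.topology!r}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp_s - self.frames[0].timestamp_s

    def downsampled(self, target_fps: float) -> "LandmarkSequence":
        """Keep every k-th frame so the effective rate is <= target_fps."""
        if target_fps <= 0:
            raise ValueError("target_fps must be positive")
        step = max(1, math.ceil(self.fps / target_fps))
        return LandmarkSequence(
            frames=self.frames[::step],
            fps=self.fps / step,
            topology=self.topology,
            subject_id=self.subject_id,
            condition=self.condition,
            max_fps=self.max_fps,
        )


def smooth_landmarks(seq: LandmarkSequence, window: int) -> LandmarkSequence:
    """Centred moving-average smoothing of landmark coordinates over
    ``window`` frames (visibilities take the window minimum). Intended for
    noisy video-derived landmarks; off by default since frames are scored
    independently."""
    if window <= 1:
        return seq
    half = window // 2
    n = len(seq.frames)
    new_frames = []
    for i, fr in enumerate(seq.frames):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neighbours = seq.frames[lo:hi]
        lms = {}
        for name, lm in fr.landmarks.items():
            others = [f.landmarks[name] for f in neighbours if name in f.landmarks]
            lms[name] = Landmark(
                name=name,
                x=sum(o.x for o in others) / len(others),
                y=sum(o.y for o in others) / len(others),
                z=sum(o.z for o in others) / len(others),
                visibility=min(o.visibility for o in others),
            )
        new_frames.append(
            PoseFrame(frame_index=fr.frame_index, timestamp_s=fr.timestamp_s, landmarks=lms)
        )
    return LandmarkSequence(
        frames=new_frames,
        fps=seq.fps,
        topology=seq.topology,
        subject_id=seq.subject_id,
        condition=seq.condition,
        max_fps=seq.max_fps,
    )


def _check_core_coverage(seq: LandmarkSequence) -> None:
    """Reject sequences where most frames cannot be scored at all."""
    if not seq.frames:
        return
    topo = get_topology(seq.topology)
    n_bad = sum(
        1 for fr in seq.frames
        if any(name not in fr.landmarks for name in topo.required_core)
    )
    if n_bad > 0.5 * len(seq.frames):
        raise LandmarkFileError(
            f"{n_bad}/{len(seq.frames)} frames are missing required core "
            "landmarks; file is not scorable"
        )


def write_landmark_file(
    seq: LandmarkSequence,
    path: str | Path,
    format: Literal["json", "csv"] = "json",
) -> Path:
    """Write a sequence to disk. Bit-stable for identical input."""
    if not seq.frames:
        raise ValueError("refusing to write a sequence with no frames")
    path = Path(path)
    if format == "json":
        doc = {
            "topology": seq.topology,
            "fps": seq.fps,
            "subject_id": seq.subject_id,
            "condition": seq.condition,
            "frames": [
                {
                    "frame_index": fr.frame_index,
                    "timestamp_s": fr.timestamp_s,
                    "landmarks": {
                        name: {
                            "x": lm.x, "y": lm.y, "z": lm.z,
                            "visibility": lm.visibility,
                        }
                        for name, lm in sorted(fr.landmarks.items())
                    },
                }
                for fr in seq.frames
            ],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")
    elif format == "csv":
        lines = [
            f"#topology={seq.topology}",
            f"#fps={seq.fps!r}",
            f"#subject_id={seq.subject_id}",
            f"#condition={seq.condition}",
            "frame_index,timestamp_s,landmark,x,y,z,visibility",
        ]
        for fr in seq.frames:
            for name, lm in sorted(fr.landmarks.items()):
                lines.append(
                    f"{fr.frame_index},{fr.timestamp_s!r},{name},"
                    f"{lm.x!r},{lm.y!r},{lm.z!r},{lm.visibility!r}"
                )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_landmark_file(
    path: str | Path,
    format: Literal["json", "csv"] | None = None,
) -> LandmarkSequence:
    """Read and validate a landmark file.

    ``format`` defaults to the file suffix. Unknown landmark names, duplicate
    or disordered frames and decreasing timestamps are rejected; a file whose
    frames mostly lack core landmarks raises :class:`LandmarkFileError`.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        seq = _read_json(path)
    elif format == "csv":
        seq = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_core_coverage(seq)
    return seq


def _read_json(path: Path) -> LandmarkSequence:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkFileError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        frames = [
            PoseFrame(
                frame_index=int(fr["frame_index"]),
                timestamp_s=float(fr["timestamp_s"]),
                landmarks={
                    name: Landmark(
                        name=name,
                        x=float(v["x"]), y=float(v["y"]), z=float(v["z"]),
                        visibility=float(v.get("visibility", 1.0)),
                    )
                    for name, v in fr["landmarks"].items()
                },
            )
            for fr in doc["frames"]
        ]
        return LandmarkSequence(
            frames=frames,
            fps=float(doc["fps"]),
            topology=str(doc.get("topology", BLAZEPOSE.name)),
            subject_id=str(doc.get("subject_id", "")),
            condition=str(doc.get("condition", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ValueError) and not isinstance(exc, LandmarkFileError):
            raise LandmarkFileError(f"{path}: {exc}") from exc
        raise LandmarkFileError(f"{path}: malformed record ({exc})") from exc


def _read_csv(path: Path) -> LandmarkSequence:
    meta = {"topology": BLAZEPOSE.name, "fps": "", "subject_id": "", "condition": ""}
    by_frame: dict[int, dict[str, Landmark]] = {}
    timestamps: dict[int, float] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            expected = "frame_index,timestamp_s,landmark,x,y,z,visibility"
            if line.replace(" ", "") != expected:
                raise LandmarkFileError(
                    f"{path}:{lineno}: expected header {expected!r}, got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise LandmarkFileError(
                f"{path}:{lineno}: expected 7 fields, got {len(parts)}"
            )
        try:
            idx = int(parts[0])
            t = float(parts[1])
            name = parts[2]
            lm = Landmark(
                name=name,
                x=float(parts[3]), y=float(parts[4]), z=float(parts[5]),
                visibility=float(parts[6]),
            )
        except ValueError as exc:
            raise LandmarkFileError(f"{path}:{lineno}: {exc}") from exc
        if idx in timestamps and timestamps[idx] != t:
            raise LandmarkFileError(
                f"{path}:{lineno}: frame {idx} has conflicting timestamps"
            )
        timestamps[idx] = t
        by_frame.setdefault(idx, {})[name] = lm
    if not header_seen:
        raise LandmarkFileError(f"{path}: missing header row")
    if not by_frame:
        raise LandmarkFileError(f"{path}: no frame records")
    if not meta["fps"]:
        raise LandmarkFileError(f"{path}: missing #fps metadata line")
    frames = [
        PoseFrame(frame_index=i, timestamp_s=timestamps[i], landmarks=lms)
        for i, lms in sorted(by_frame.items())
    ]
    try:
        return LandmarkSequence(
            frames=frames,
            fps=float(meta["fps"]),
            topology=meta["topology"],
            subject_id=meta["subject_id"],
            condition=meta["condition"],
        )
    except ValueError as exc:
        raise LandmarkFileError(f"{path}: {exc}") from exc
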