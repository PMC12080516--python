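"""Pose-backend adapter contract.

An adapter is any callable that takes a video path and returns a
:class:`~ergoreba.pose_model.LandmarkSequence` in the canonical frame
(metres, +Y up, origin at mid-hip per frame) using a topology that maps the
required core names. Video decoding and pose estimation are entirely the
adapter's concern — this package never imports an estimator itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Protocol

from .pose_model import LandmarkSequence


class PoseBackend(Protocol):
    def __call__(self, video_path: str | Path) -> LandmarkSequence: ...


_BACKENDS: dict[str, PoseBackend] = {}


def register_backend(name: str, backend: PoseBackend) -> None:
    _BACKENDS[name] = backend


def get_backend(name: str) -> PoseBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"no pose backend registered under {name!r}; "
            f"available: {sorted(_BACKENDS) or 'none'}"
        ) from None
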