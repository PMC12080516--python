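import numpy as np
import pytest

import ergoreba as eg


@pytest.fixture
def neutral_frame():
    return eg.make_posed_skeleton(eg.PostureSpec())


@pytest.fixture
def pipeline_config():
    """Activity pinned off so table lookups fully determine scores."""
    return eg.PipelineConfig(activity=eg.ActivityConfig(mode="off"))


@pytest.fixture
def fixture_sequence():
    """A 120-frame noise-free synthetic optimal-bed sequence."""
    return eg.make_scenario_sequence(
        eg.ScenarioConfig("optimal_bed", n_frames=120, fps=30.0, seed=42),
        subject_height_cm=175.0,
        subject_id="fixture",
    )


def rotate_frame(frame, deg):
    """Rigidly rotate a whole frame about the vertical axis."""
    a = np.radians(deg)
    R = np.array([
        [np.cos(a), 0.0, np.sin(a)],
        [0.0, 1.0, 0.0],
        [-np.sin(a), 0.0, np.cos(a)],
    ])
    lms = {}
    for name, lm in frame.landmarks.items():
        p = R @ np.array(lm.xyz)
        lms[name] = eg.Landmark(name, float(p[0]), float(p[1]), float(p[2]), lm.visibility)
    return eg.PoseFrame(frame.frame_index, frame.timestamp_s, lms)


def translate_frame(frame, offset):
    lms = {
        name: eg.Landmark(
            name, lm.x + offset[0], lm.y + offset[1], lm.z + offset[2], lm.visibility
        )
        for name, lm in frame.landmarks.items()
    }
    return eg.PoseFrame(frame.frame_index, frame.timestamp_s, lms)


_MIRROR = {"left": "right", "right": "left"}


def mirror_frame(frame):
    """Reflect across the sagittal plane: negate x and swap left/right names."""
    lms = {}
    for name, lm in frame.landmarks.items():
        parts = name.split("_", 1)
        if parts[0] in _MIRROR:
            new = f"{_MIRROR[parts[0]]}_{parts[1]}"
        elif name.startswith("mouth_"):
            new = f"mouth_{_MIRROR[name.split('_')[1]]}"
        else:
            new = name
        lms[new] = eg.Landmark(new, -lm.x, lm.y, lm.z, lm.visibility)
    return eg.PoseFrame(frame.frame_index, frame.timestamp_s, lms)
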