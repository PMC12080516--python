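"""Joint-angle extraction: closed-form cases, generator round-trips and
rigid-motion invariances."""

import dataclasses

import numpy as np
import pytest

import ergoreba as eg
from ergoreba.kinematics import (
    DegenerateGeometryError,
    arm_angles,
    leg_angles,
    neck_angles,
    trunk_angles,
)

from conftest import mirror_frame, rotate_frame, translate_frame


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_closed_form(self, u, v, expected):
        assert eg.angle_between(np.array(u), np.array(v)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            eg.angle_between(np.zeros(3), np.array([1.0, 0, 0]))


class TestBodyAxes:
    def test_facing_forward(self, neutral_frame):
        right, forward, up = eg.body_axes(neutral_frame)
        assert forward == pytest.approx([0, 0, 1], abs=1e-12)
        assert up == pytest.approx([0, 1, 0])
        assert right == pytest.approx([-1, 0, 0], abs=1e-12)

    def test_mirroring_flips_nothing_but_handedness(self, neutral_frame):
        # reflected subject still faces +Z; the right axis tracks the new right side
        right, forward, up = eg.body_axes(mirror_frame(neutral_frame))
        assert forward == pytest.approx([0, 0, 1], abs=1e-12)

    def test_half_turn_flips_forward(self, neutral_frame):
        right, forward, up = eg.body_axes(rotate_frame(neutral_frame, 180.0))
        assert forward == pytest.approx([0, 0, -1], abs=1e-9)

    def test_orthonormal_under_random_rotations(self, neutral_frame):
        rng = np.random.default_rng(11)
        for _ in range(50):
            fr = rotate_frame(neutral_frame, rng.uniform(0, 360))
            r, f, u = eg.body_axes(fr)
            for v in (r, f, u):
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            assert abs(np.dot(r, f)) < 1e-9
            assert abs(np.dot(r, u)) < 1e-9
            assert abs(np.dot(f, u)) < 1e-9

    def test_coincident_hips_degenerate(self, neutral_frame):
        lms = dict(neutral_frame.landmarks)
        lh = lms["left_hip"]
        lms["right_hip"] = eg.Landmark("right_hip", lh.x, lh.y, lh.z)
        with pytest.raises(DegenerateGeometryError):
            eg.body_axes(eg.PoseFrame(0, 0.0, lms))


class TestSubAngleConstructions:
    def test_vertical_trunk_neutral(self, neutral_frame):
        t = trunk_angles(neutral_frame)
        assert t.flexion_deg == pytest.approx(0.0, abs=0.5)
        assert not t.twisted and not t.side_bent

    def test_trunk_lean_recovered(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(trunk_flexion_deg=35.0))
        assert trunk_angles(fr).flexion_deg == pytest.approx(35.0, abs=0.5)

    def test_trunk_extension_negative(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(trunk_flexion_deg=-15.0))
        assert trunk_angles(fr).flexion_deg == pytest.approx(-15.0, abs=0.5)

    def test_trunk_twist_flag(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(trunk_twist_deg=25.0))
        assert trunk_angles(fr).twisted
        fr = eg.make_posed_skeleton(eg.PostureSpec(trunk_twist_deg=10.0))
        assert not trunk_angles(fr).twisted

    def test_trunk_side_bend_flag(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(trunk_side_bend_deg=20.0))
        t = trunk_angles(fr)
        assert t.side_bent
        # lateral lean alone is not sagittal flexion
        assert t.flexion_deg == pytest.approx(0.0, abs=0.5)

    def test_neck_aligned_with_trunk_neutral(self):
        fr = eg.make_posed_skeleton(
            eg.PostureSpec(trunk_flexion_deg=30.0, neck_flexion_deg=0.0)
        )
        n = neck_angles(fr)
        assert n.flexion_deg == pytest.approx(0.0, abs=0.5)
        assert not n.twisted and not n.side_bent

    def test_neck_flexion_recovered(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(neck_flexion_deg=25.0))
        assert neck_angles(fr).flexion_deg == pytest.approx(25.0, abs=0.5)

    def test_neck_twist_flag(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(neck_twist_deg=30.0))
        assert neck_angles(fr).twisted

    def test_neck_falls_back_to_nose(self, neutral_frame):
        lms = {
            k: (eg.Landmark(k, v.x, v.y, v.z, 0.1) if k.endswith("_ear") else v)
            for k, v in neutral_frame.landmarks.items()
        }
        n = neck_angles(eg.PoseFrame(0, 0.0, lms))
        assert np.isfinite(n.flexion_deg)

    def test_neck_unusable_without_head(self, neutral_frame):
        lms = {
            k: v for k, v in neutral_frame.landmarks.items()
            if k not in ("left_ear", "right_ear", "nose")
        }
        with pytest.raises(DegenerateGeometryError, match="neck"):
            neck_angles(eg.PoseFrame(0, 0.0, lms))

    def test_hanging_arm_neutral(self, neutral_frame):
        for side in ("left", "right"):
            a = arm_angles(neutral_frame, side)
            assert a.upper_arm_elevation_deg == pytest.approx(0.0, abs=0.5)
            assert a.elbow_flexion_deg == pytest.approx(0.0, abs=0.5)
            assert not a.abducted and not a.shoulder_raised

    def test_arm_angles_recovered(self):
        fr = eg.make_posed_skeleton(
            eg.PostureSpec(arm_elevation_deg_right=60.0, elbow_flexion_deg_right=80.0)
        )
        a = arm_angles(fr, "right")
        assert a.upper_arm_elevation_deg == pytest.approx(60.0, abs=0.5)
        assert a.elbow_flexion_deg == pytest.approx(80.0, abs=0.5)

    def test_sideways_arm_abducted(self):
        fr = eg.make_posed_skeleton(
            eg.PostureSpec(arm_elevation_deg_right=90.0, arm_abducted_right=True)
        )
        a = arm_angles(fr, "right")
        assert a.upper_arm_elevation_deg == pytest.approx(90.0, abs=0.5)
        assert a.abducted

    def test_forward_arm_not_abducted(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(arm_elevation_deg_right=90.0))
        assert not arm_angles(fr, "right").abducted

    def test_raised_shoulder_flag(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(shoulder_tilt_deg=15.0))
        assert arm_angles(fr, "right").shoulder_raised
        assert not arm_angles(fr, "left").shoulder_raised

    def test_wrist_flexion_recovered(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(wrist_flexion_deg_left=30.0))
        a = arm_angles(fr, "left")
        assert a.wrist_flexion_deg == pytest.approx(30.0, abs=0.5)

    def test_wrist_absent_without_hand_landmarks(self, neutral_frame):
        lms = {
            k: v for k, v in neutral_frame.landmarks.items()
            if not k.endswith(("_index", "_pinky", "_thumb"))
        }
        a = arm_angles(eg.PoseFrame(0, 0.0, lms), "right")
        assert a.wrist_flexion_deg is None

    def test_straight_standing_legs(self, neutral_frame):
        l = leg_angles(neutral_frame)
        assert l.knee_flexion_deg_left == pytest.approx(0.0, abs=0.5)
        assert l.knee_flexion_deg_right == pytest.approx(0.0, abs=0.5)
        assert not l.unilateral_support

    def test_crouch_recovered_bilateral(self):
        fr = eg.make_posed_skeleton(
            eg.PostureSpec(knee_flexion_deg_left=45.0, knee_flexion_deg_right=45.0)
        )
        l = leg_angles(fr)
        assert l.knee_flexion_deg_left == pytest.approx(45.0, abs=0.5)
        assert not l.unilateral_support

    def test_raised_ankle_unilateral(self):
        fr = eg.make_posed_skeleton(eg.PostureSpec(raised_ankle_m=0.15))
        assert leg_angles(fr).unilateral_support
        fr = eg.make_posed_skeleton(eg.PostureSpec(raised_ankle_m=0.05))
        assert not leg_angles(fr).unilateral_support


class TestComputeJointAngles:
    def test_neutral_all_zero_no_flags(self, neutral_frame):
        ja = eg.compute_joint_angles(neutral_frame)
        for v in ja.tracked().values():
            assert v == pytest.approx(0.0, abs=0.5)
        for f in dataclasses.fields(ja):
            if f.type is bool or isinstance(getattr(ja, f.name), bool):
                assert getattr(ja, f.name) is False

    def test_deterministic(self, neutral_frame):
        assert eg.compute_joint_angles(neutral_frame) == eg.compute_joint_angles(
            neutral_frame
        )

    def test_random_posture_recovery(self):
        """Noise-free generator postures come back within half a degree."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            spec = eg.random_posture_spec(rng)
            ja = eg.compute_joint_angles(eg.make_posed_skeleton(spec))
            assert ja.trunk_flexion_deg == pytest.approx(spec.trunk_flexion_deg, abs=0.5)
            assert ja.neck_flexion_deg == pytest.approx(spec.neck_flexion_deg, abs=0.5)
            assert ja.upper_arm_elevation_deg_left == pytest.approx(
                spec.arm_elevation_deg_left, abs=0.5
            )
            assert ja.upper_arm_elevation_deg_right == pytest.approx(
                spec.arm_elevation_deg_right, abs=0.5
            )
            assert ja.elbow_flexion_deg_left == pytest.approx(
                spec.elbow_flexion_deg_left, abs=0.5
            )
            assert ja.knee_flexion_deg_left == pytest.approx(
                spec.knee_flexion_deg_left, abs=0.5
            )
            assert ja.knee_flexion_deg_right == pytest.approx(
                spec.knee_flexion_deg_right, abs=0.5
            )
            assert abs(ja.wrist_flexion_deg_left) == pytest.approx(
                abs(spec.wrist_flexion_deg_left), abs=0.5
            )


class TestInvariances:
    def _angles(self, frame):
        ja = eg.compute_joint_angles(frame)
        return ja.tracked(), {
            f.name: getattr(ja, f.name)
            for f in dataclasses.fields(ja)
            if isinstance(getattr(ja, f.name), bool)
        }

    def test_rotation_about_vertical(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            spec = eg.random_posture_spec(rng)
            fr = eg.make_posed_skeleton(spec)
            base_angles, base_flags = self._angles(fr)
            rot_angles, rot_flags = self._angles(rotate_frame(fr, rng.uniform(0, 360)))
            for k in base_angles:
                assert rot_angles[k] == pytest.approx(base_angles[k], abs=1e-6)
            assert rot_flags == base_flags

    def test_translation(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            fr = eg.make_posed_skeleton(eg.random_posture_spec(rng))
            base_angles, base_flags = self._angles(fr)
            off = rng.uniform(-5, 5, size=3)
            tr_angles, tr_flags = self._angles(translate_frame(fr, off))
            for k in base_angles:
                assert tr_angles[k] == pytest.approx(base_angles[k], abs=1e-6)
            assert tr_flags == base_flags

    def test_mirror_swaps_sides(self):
        rng = np.random.default_rng(23)
        swap = lambda k: k.replace("left", "TMP").replace("right", "left").replace("TMP", "right")
        for _ in range(20):
            fr = eg.make_posed_skeleton(eg.random_posture_spec(rng))
            base = eg.compute_joint_angles(fr)
            mirr = eg.compute_joint_angles(mirror_frame(fr))
            for name in (
                "upper_arm_elevation_deg", "elbow_flexion_deg", "knee_flexion_deg",
            ):
                for side in ("left", "right"):
                    other = "right" if side == "left" else "left"
                    assert getattr(mirr, f"{name}_{side}") == pytest.approx(
                        getattr(base, f"{name}_{other}"), abs=1e-6
                    )
            for name in ("arm_abducted", "shoulder_raised"):
                for side in ("left", "right"):
                    other = "right" if side == "left" else "left"
                    assert getattr(mirr, f"{name}_{side}") == getattr(base, f"{name}_{other}")
            assert mirr.trunk_flexion_deg == pytest.approx(base.trunk_flexion_deg, abs=1e-6)
            assert mirr.neck_flexion_deg == pytest.approx(base.neck_flexion_deg, abs=1e-6)
            assert mirr.trunk_twisted == base.trunk_twisted
            assert mirr.neck_twisted == base.neck_twisted
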