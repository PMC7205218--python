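"""Frames from marker triplets, YXZ Cardan angles, local-frame expression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fodeform.exceptions import DegenerateGeometryError, ParameterError
from fodeform.kinematics import (
    CardanAngles,
    MarkerTrajectorySet,
    RigidFrame,
    cardan_yxz_from_rotation,
    express_in_local_frame,
    frame_from_three_markers,
    interpolate_gaps,
    lowpass_filter,
    relative_cardan,
    rotation_from_cardan_yxz,
    triad_orientation,
)


def random_rotation(rng):
    return rotation_from_cardan_yxz(
        np.array(
            [
                rng.uniform(-np.pi, np.pi),
                rng.uniform(-np.pi / 2 + 0.05, np.pi / 2 - 0.05),
                rng.uniform(-np.pi, np.pi),
            ]
        )
    )


class TestFrameFromThreeMarkers:
    def test_canonical_configuration_gives_identity(self):
        fr = frame_from_three_markers([0, 0, 0], [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(fr.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fr.origin, np.zeros(3), atol=1e-12)
        assert fr.is_valid()

    def test_rigid_transform_oracle(self, rng):
        """Rigidly moving the markers moves the frame by the same transform."""
        p1, p2, p3 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        base = frame_from_three_markers(p1, p2, p3)
        for _ in range(100):
            R = random_rotation(rng)
            t = rng.uniform(-100, 100, 3)
            fr = frame_from_three_markers(R @ p1 + t, R @ p2 + t, R @ p3 + t)
            np.testing.assert_allclose(fr.rotation, R @ base.rotation, atol=1e-9)
            np.testing.assert_allclose(fr.origin, R @ base.origin + t, atol=1e-9)

    @pytest.mark.parametrize(
        "p2,p3",
        [
            ([0, 0, 0], [0, 1, 0]),  # coincident p1 == p2
            ([1, 0, 0], [2, 0, 0]),  # collinear
        ],
    )
    def test_degenerate_geometry_raises(self, p2, p3):
        with pytest.raises(DegenerateGeometryError):
            frame_from_three_markers([0, 0, 0], p2, p3)

    def test_error_names_offending_markers(self):
        with pytest.raises(DegenerateGeometryError, match="M1/M2/M3"):
            frame_from_three_markers(
                [0, 0, 0], [0, 0, 0], [1, 1, 1], labels=("M1", "M2", "M3")
            )


class TestCardanYXZ:
    def test_identity_rotation_gives_zero_angles(self):
        ang = cardan_yxz_from_rotation(np.eye(3))
        np.testing.assert_allclose(ang.as_array(), 0.0, atol=1e-12)

    def test_known_triplet_round_trip(self):
        ang = cardan_yxz_from_rotation(rotation_from_cardan_yxz(np.array([0.2, -0.4, 0.9])))
        np.testing.assert_allclose(ang.as_array(), [0.2, -0.4, 0.9], atol=1e-9)

    def test_pure_y_rotation(self):
        R = rotation_from_cardan_yxz(np.array([np.pi / 2, 0, 0]))
        ang = cardan_yxz_from_rotation(R)
        np.testing.assert_allclose(ang.as_array(), [np.pi / 2, 0, 0], atol=1e-9)

    def test_round_trip_1000_random_rotations(self, rng):
        for _ in range(1000):
            truth = np.array(
                [
                    rng.uniform(-np.pi, np.pi),
                    rng.uniform(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3),
                    rng.uniform(-np.pi, np.pi),
                ]
            )
            R = rotation_from_cardan_yxz(truth)
            back = cardan_yxz_from_rotation(R)
            np.testing.assert_allclose(back.as_array(), truth, atol=1e-9)
            np.testing.assert_allclose(rotation_from_cardan_yxz(back), R, atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ty=st.floats(-3.1, 3.1),
        tx=st.floats(-1.5, 1.5),
        tz=st.floats(-3.1, 3.1),
    )
    def test_compose_decompose_identity_property(self, ty, tx, tz):
        R = rotation_from_cardan_yxz(np.array([ty, tx, tz]))
        np.testing.assert_allclose(
            rotation_from_cardan_yxz(cardan_yxz_from_rotation(R)), R, atol=1e-9
        )

    def test_gimbal_lock_flagged_and_resolved_with_zero_z(self):
        R = rotation_from_cardan_yxz(np.array([0.3, np.pi / 2, 0.0]))
        ang = cardan_yxz_from_rotation(R)
        assert ang.gimbal_lock
        assert ang.theta_z == 0.0
        np.testing.assert_allclose(rotation_from_cardan_yxz(ang), R, atol=1e-9)

    def test_rejects_non_rotation(self):
        with pytest.raises(ParameterError):
            cardan_yxz_from_rotation(2 * np.eye(3))


class TestRelativeCardan:
    def test_self_relative_is_zero(self):
        fr = RigidFrame(rotation_from_cardan_yxz(np.array([0.3, 0.1, -0.2])), np.zeros(3))
        np.testing.assert_allclose(relative_cardan(fr, fr).as_array(), 0.0, atol=1e-12)

    def test_known_relative_angles_recovered(self):
        back = RigidFrame(rotation_from_cardan_yxz(np.array([0.5, -0.2, 0.1])), np.zeros(3))
        rel = np.array([0.12, -0.31, 0.44])
        triad = RigidFrame(back.rotation @ rotation_from_cardan_yxz(rel), np.zeros(3))
        np.testing.assert_allclose(relative_cardan(triad, back).as_array(), rel, atol=1e-9)

    def test_triad_orientation_recovers_synthetic_tilt(self, rng):
        m = np.array([[0.0, 0, 0], [20.0, 0, 0], [0, 0, 20.0]])
        base = triad_orientation(*m)
        for _ in range(20):
            R = random_rotation(rng)
            tilted = triad_orientation(*(m @ R.T))
            np.testing.assert_allclose(tilted.rotation, R @ base.rotation, atol=1e-9)

    def test_missing_triad_marker_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            triad_orientation([0, 0, 0], [np.nan, 0, 0], [0, 0, 1])


class TestLocalFrameExpression:
    def test_point_at_origin_maps_to_zero(self):
        fr = RigidFrame(rotation_from_cardan_yxz(np.array([1.0, 0.3, -0.7])), np.array([5.0, 6, 7]))
        np.testing.assert_allclose(express_in_local_frame(fr.origin, fr), 0.0, atol=1e-12)

    def test_identity_frame_is_no_op(self, rng):
        pts = rng.uniform(-10, 10, (7, 3))
        np.testing.assert_allclose(express_in_local_frame(pts, RigidFrame.identity()), pts)

    def test_invariance_under_common_rigid_motion(self, rng):
        """Local coordinates ignore any rigid motion applied to the whole scene."""
        markers = rng.uniform(-50, 50, (3, 3))
        pts = rng.uniform(-100, 100, (20, 3))
        ref = express_in_local_frame(pts, frame_from_three_markers(*markers))
        for _ in range(100):
            R = random_rotation(rng)
            t = rng.uniform(-500, 500, 3)
            moved = express_in_local_frame(
                pts @ R.T + t, frame_from_three_markers(*(markers @ R.T + t))
            )
            np.testing.assert_allclose(moved, ref, atol=1e-9)


class TestTrajectoryHygiene:
    def test_short_gap_linearly_interpolated(self):
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = np.arange(10.0)
        pos[4:6, 0, 0] = np.nan
        mts = MarkerTrajectorySet(["A"], pos)
        filled, kept = interpolate_gaps(mts, max_gap=10)
        assert len(kept) == 10
        np.testing.assert_allclose(filled.positions[:, 0, 0], np.arange(10.0))

    def test_long_gap_drops_frames(self):
        pos = np.zeros((20, 1, 3))
        pos[5:17, 0, 1] = np.nan
        filled, kept = interpolate_gaps(MarkerTrajectorySet(["A"], pos), max_gap=10)
        assert filled.n_frames == 8
        assert set(kept) == set(range(5)) | set(range(17, 20))

    def test_lowpass_attenuates_noise_keeps_level(self, rng):
        pos = 3.0 + rng.normal(0, 0.1, (500, 2, 3))
        out = lowpass_filter(MarkerTrajectorySet(["A", "B"], pos), cutoff=8.0)
        assert out.positions.std() < 0.5 * pos.std()
        np.testing.assert_allclose(out.positions.mean(), 3.0, atol=0.01)

    def test_lowpass_rejects_bad_cutoff(self):
        mts = MarkerTrajectorySet(["A"], np.zeros((10, 1, 3)), rate=100.0)
        with pytest.raises(ParameterError):
            lowpass_filter(mts, cutoff=60.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ParameterError):
            MarkerTrajectorySet(["A", "A"], np.zeros((2, 2, 3)))
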