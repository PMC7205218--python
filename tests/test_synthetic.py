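"""The deformable-orthosis simulator: geometry, load response, sessions."""

import numpy as np
import pytest

from fodeform.exceptions import ParameterError
from fodeform.kinematics import triad_orientation
from fodeform.synthetic import (
    REGULAR_STIFFNESS,
    SPORT_STIFFNESS,
    make_calibration_series,
    make_fo_model,
    simulate_point_load,
    simulate_training_session,
    simulate_walking_session,
    surface_deformation,
)


class TestFoModel:
    def test_geometry_counts(self, sport_fo):
        assert sport_fo.surface_points_static.shape == (55, 3)
        assert len(sport_fo.triad_labels) == 18  # 6 triads x 3 markers
        assert sport_fo.triad_reference_markers().shape == (18, 3)

    def test_determinism(self):
        a = make_fo_model(seed=3)
        b = make_fo_model(seed=3)
        np.testing.assert_array_equal(a.surface_points_static, b.surface_points_static)

    def test_sport_softer_than_regular(self, sport_fo, regular_fo):
        """Any fixed load dents the compliant sport model more deeply."""
        assert SPORT_STIFFNESS < REGULAR_STIFFNESS
        pt = np.array([100.0, -20.0])
        w_sport = surface_deformation(sport_fo, pt, 40.0)
        w_reg = surface_deformation(regular_fo, pt, 40.0)
        assert abs(w_sport.min()) > abs(w_reg.min())

    @pytest.mark.parametrize("kwargs", [{"stiffness_k": -1.0}, {"kernel_sigma": 0.0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            make_fo_model(**kwargs)


class TestPointLoad:
    def test_zero_force_is_reference_configuration(self, sport_fo):
        surface, triads, poses, w = simulate_point_load(sport_fo, [100.0, 0.0], 0.0)
        np.testing.assert_array_equal(w, 0.0)
        np.testing.assert_allclose(surface, sport_fo.surface_points_static)
        np.testing.assert_allclose(triads, sport_fo.triad_reference_markers(), atol=1e-12)

    def test_displacement_at_load_point_is_force_over_stiffness(self, sport_fo):
        # Place the load exactly on an unclamped surface point: kernel value 1.
        target = sport_fo.surface_points_static[30]
        _, _, _, w = simulate_point_load(sport_fo, target[[0, 2]], 25.0)
        np.testing.assert_allclose(w[30], -25.0 / sport_fo.stiffness_k, rtol=1e-12)

    def test_linearity_in_force(self, sport_fo):
        pt = [120.0, 10.0]
        _, _, _, w1 = simulate_point_load(sport_fo, pt, 30.0)
        _, _, _, w2 = simulate_point_load(sport_fo, pt, 60.0)
        np.testing.assert_allclose(w2, 2 * w1, atol=1e-12)

    def test_heel_cup_clamped(self, sport_fo):
        _, _, _, w = simulate_point_load(sport_fo, [10.0, 0.0], 80.0)
        assert np.all(w[sport_fo.heel_fixed_mask] == 0.0)
        assert w[~sport_fo.heel_fixed_mask].min() < 0

    def test_negative_force_rejected(self, sport_fo):
        with pytest.raises(ParameterError):
            simulate_point_load(sport_fo, [100.0, 0.0], -1.0)

    def test_point_outside_footprint_rejected(self, sport_fo):
        with pytest.raises(ParameterError):
            simulate_point_load(sport_fo, [400.0, 0.0], 10.0)

    def test_triad_response_smooth_in_force(self, sport_fo):
        """Noise-free triad pose varies continuously with the load."""
        pt = [70.0, -25.0]
        forces = np.linspace(0, 60, 25)
        angles = []
        for fval in forces:
            _, _, poses, _ = simulate_point_load(sport_fo, pt, fval)
            angles.append([np.arccos(np.clip(p.rotation[1, 1], -1, 1)) for p in poses])
        diffs = np.abs(np.diff(np.asarray(angles), axis=0))
        assert diffs.max() < 0.05  # no jumps between consecutive force steps


class TestTrainingSession:
    def test_all_ten_regions_loaded(self, sport_fo):
        scene = simulate_training_session(sport_fo, n_loads_per_region=1, seed=5)
        loaded = scene.load_region[scene.load_force >= 0.1]
        assert len(set(loaded.tolist())) == 10

    def test_unloaded_frames_interleaved(self, small_training_scene):
        assert (small_training_scene.load_force < 0.1).sum() > 0

    def test_zero_ground_truth_on_zero_load(self, small_training_scene):
        sc = small_training_scene
        unloaded = sc.load_force == 0.0
        assert np.all(sc.ground_truth_deformation[unloaded] == 0.0)

    def test_heel_points_never_deform(self, small_training_scene):
        sc = small_training_scene
        assert np.all(sc.ground_truth_deformation[:, sc.fo.heel_fixed_mask] == 0.0)

    def test_noise_free_frames_match_point_load_exactly(self, sport_fo):
        scene = simulate_training_session(sport_fo, n_loads_per_region=1, noise_sd=0.0, seed=2)
        idx = np.nonzero(scene.load_force >= 0.1)[0][::37]
        for fi in idx:
            surface, triads, _, w = simulate_point_load(
                sport_fo, scene.load_point[fi], scene.load_force[fi]
            )
            np.testing.assert_allclose(scene.frames.positions[fi, :55], surface, atol=1e-12)
            np.testing.assert_allclose(scene.frames.positions[fi, 55:73], triads, atol=1e-12)
            np.testing.assert_allclose(scene.ground_truth_deformation[fi], w, atol=1e-12)

    def test_determinism(self, sport_fo):
        a = simulate_training_session(sport_fo, n_loads_per_region=1, seed=11)
        b = simulate_training_session(sport_fo, n_loads_per_region=1, seed=11)
        np.testing.assert_array_equal(a.frames.positions, b.frames.positions)

    def test_training_forces_cover_walking_peaks(self, sport_fo):
        """A 120 N training range brackets <= 35 N regional walking peaks."""
        scene = simulate_training_session(
            sport_fo, n_loads_per_region=4, force_range=(0.0, 120.0), seed=3
        )
        walk = simulate_walking_session(sport_fo, n_steps=6, peak_force=30.0, seed=4)
        for reg in set(walk.load_region[walk.load_force > 0].tolist()):
            w_peak = walk.load_force[walk.load_region == reg].max()
            t_peak = scene.load_force[scene.load_region == reg].max()
            assert w_peak <= 35.0
            assert t_peak >= w_peak

    def test_invalid_parameters(self, sport_fo):
        with pytest.raises(ParameterError):
            simulate_training_session(sport_fo, n_loads_per_region=0)
        with pytest.raises(ParameterError):
            simulate_training_session(sport_fo, force_range=(50.0, 10.0))


class TestWalkingSession:
    def test_event_count_matches_steps(self, sport_fo):
        scene = simulate_walking_session(sport_fo, n_steps=5, seed=1)
        assert len(scene.stance_events) == 5
        for hs, to in scene.stance_events:
            assert to > hs

    def test_swing_frames_unloaded(self, small_walking_scene):
        sc = small_walking_scene
        in_stance = np.zeros(sc.frames.n_frames, bool)
        for hs, to in sc.stance_events:
            in_stance[hs:to] = True
        assert np.all(sc.load_force[~in_stance] == 0.0)
        assert np.all(sc.ground_truth_deformation[~in_stance] == 0.0)

    def test_midstance_depression_is_medial(self, sport_fo):
        """The arch collapse pattern: negative deformation on medial points at midstance."""
        scene = simulate_walking_session(sport_fo, n_steps=2, noise_sd=0.0, seed=3)
        hs, to = scene.stance_events[0]
        mid = (hs + to) // 2
        pts = sport_fo.surface_points_static
        medial_mid = (pts[:, 2] < -10) & (pts[:, 0] > 60) & (pts[:, 0] < 140)
        assert scene.ground_truth_deformation[mid, medial_mid].min() < -1.0

    def test_surface_markers_flagged_hidden(self, small_walking_scene):
        assert set(small_walking_scene.hidden_labels) == set(
            small_walking_scene.fo.surface_labels
        )

    def test_walking_triads_match_training_deformation_model(self, sport_fo):
        """Without rigid motion and noise, a walking frame's triad orientations
        equal those of a static load at the same instantaneous (point, force)."""
        scene = simulate_walking_session(
            sport_fo, n_steps=1, rigid_motion_amplitude=(0.0, 0.0), noise_sd=0.0, seed=6
        )
        hs, to = scene.stance_events[0]
        for fi in range(hs, to, 13):
            _, triads, poses, _ = simulate_point_load(
                sport_fo, scene.load_point[fi], scene.load_force[fi]
            )
            np.testing.assert_allclose(scene.frames.positions[fi, 55:73], triads, atol=1e-9)
            for t in range(6):
                got = triad_orientation(*scene.frames.positions[fi, 55 + 3 * t : 58 + 3 * t])
                want = triad_orientation(*triads[3 * t : 3 * t + 3])
                np.testing.assert_allclose(got.rotation, want.rotation, atol=1e-9)

    def test_stiffness_monotonicity_on_matched_scenes(self, sport_fo, regular_fo):
        a = simulate_walking_session(sport_fo, n_steps=3, noise_sd=0.0, seed=8)
        b = simulate_walking_session(regular_fo, n_steps=3, noise_sd=0.0, seed=8)
        assert np.abs(a.ground_truth_deformation).max() > np.abs(b.ground_truth_deformation).max()


def test_calibration_series_follows_linear_law():
    raw, forces = make_calibration_series(gain=0.31, offset=2.0, noise_sd=0.0, seed=0)
    np.testing.assert_allclose(0.31 * raw + 2.0, forces, atol=1e-9)
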