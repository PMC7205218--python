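"""Rigid/non-rigid separation, stance detection and normalization, peaks."""

import numpy as np
import pytest

from fodeform.deformation import (
    DeformationField,
    StanceCycle,
    deformation_field_from_positions,
    depression_reformation,
    detect_stance,
    normalize_to_stance,
    optimal_rototranslation,
    remove_rigid_motion,
    stance_peaks,
)
from fodeform.exceptions import DegenerateGeometryError, ParameterError
from fodeform.kinematics import rotation_from_cardan_yxz


def _cloud(rng, n=55):
    return rng.uniform(-100, 100, (n, 3))


class TestOptimalRototranslation:
    def test_identity_on_equal_clouds(self, rng):
        pts = _cloud(rng)
        frame, resid = optimal_rototranslation(pts, pts)
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(frame.origin, 0.0, atol=1e-9)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_recovers_100_random_rigid_transforms(self, rng):
        pts = _cloud(rng)
        for _ in range(100):
            R = rotation_from_cardan_yxz(rng.uniform(-np.pi / 2, np.pi / 2, 3))
            t = rng.uniform(-200, 200, 3)
            frame, resid = optimal_rototranslation(pts, pts @ R.T + t)
            np.testing.assert_allclose(frame.rotation, R, atol=1e-9)
            np.testing.assert_allclose(frame.origin, t, atol=1e-9)
            np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_dent_residuals_orthogonal_to_rigid_modes(self, rng):
        """Least-squares optimality: residuals have zero resultant and a
        symmetric cross-moment with the fitted cloud (zero torque)."""
        static = _cloud(rng)
        dented = static.copy()
        dented[:5, 1] -= np.array([4.0, 3.5, 3.0, 2.5, 2.0])
        frame, resid = optimal_rototranslation(static, dented)
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-8)
        fitted = (static - static.mean(axis=0)) @ frame.rotation.T
        cross = resid.T @ fitted
        np.testing.assert_allclose(cross, cross.T, atol=1e-8)

    def test_degenerate_clouds_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            optimal_rototranslation(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            optimal_rototranslation(line, line)

    def test_remove_rigid_motion_restores_static_frame(self, rng):
        static = _cloud(rng)
        R = rotation_from_cardan_yxz(np.array([0.3, -0.2, 0.5]))
        moved = static @ R.T + np.array([5.0, 6.0, 7.0])
        np.testing.assert_allclose(remove_rigid_motion(static, moved), static, atol=1e-9)


class TestStanceDetection:
    def test_recovers_simulator_events_exactly(self, small_walking_scene):
        sc = small_walking_scene
        cycles = detect_stance(sc.load_force, rate=sc.frames.rate)
        got = [(c.heel_strike_frame, c.toe_off_frame) for c in cycles]
        assert got == sc.stance_events

    def test_zero_load_gives_no_cycles(self):
        assert detect_stance(np.zeros(200)) == []

    def test_single_square_pulse(self):
        load = np.zeros(100)
        load[10:60] = 8.0
        cycles = detect_stance(load, rate=100.0)
        assert len(cycles) == 1
        assert (cycles[0].heel_strike_frame, cycles[0].toe_off_frame) == (10, 60)

    def test_short_blips_discarded_with_warning(self):
        load = np.zeros(100)
        load[50:55] = 10.0  # 0.05 s, below the minimum stance duration
        with pytest.warns(UserWarning):
            assert detect_stance(load, rate=100.0) == []


class TestStanceNormalization:
    def test_constant_series(self):
        out = normalize_to_stance(np.full(60, 4.2), StanceCycle(0, 60))
        assert out.shape == (101,)
        np.testing.assert_allclose(out, 4.2)

    def test_linear_ramp_preserves_endpoints(self):
        out = normalize_to_stance(np.arange(50.0), StanceCycle(0, 50))
        assert out[0] == 0.0
        assert out[-1] == 49.0
        np.testing.assert_allclose(np.diff(out), np.diff(out)[0], atol=1e-9)

    def test_downsample_then_normalize_consistency(self):
        """Resampling a smooth signal through an intermediate rate changes
        the normalized curve by a negligible fraction of its amplitude."""
        t_full = np.linspace(0, 1, 6001)
        sig_full = np.sin(2 * np.pi * t_full)
        direct = normalize_to_stance(sig_full, StanceCycle(0, 6001))
        half = sig_full[::2]  # every other sample, endpoints preserved
        indirect = normalize_to_stance(half, StanceCycle(0, 3001))
        assert np.abs(direct - indirect).max() < 1e-6  # fraction of unit amplitude

    def test_degenerate_cycle_rejected(self):
        with pytest.raises(ParameterError):
            normalize_to_stance(np.arange(10.0), StanceCycle(3, 4))
        with pytest.raises(ParameterError):
            normalize_to_stance(np.arange(10.0), StanceCycle(5, 50))


class TestDepressionReformation:
    def test_sign_convention(self):
        cur = np.array([[0.0, 10.0, 0.0]])
        ref = np.array([[0.0, 12.0, 0.0]])
        assert depression_reformation(cur, ref)[0] == pytest.approx(-2.0)  # pressed down

    def test_identity_is_zero(self, rng):
        pts = _cloud(rng)
        np.testing.assert_array_equal(depression_reformation(pts, pts), 0.0)

    def test_simulator_midstance_depression_is_medial(self, sport_fo):
        from fodeform.synthetic import simulate_point_load

        surface, _, _, _ = simulate_point_load(sport_fo, [95.0, -20.0], 30.0)
        aligned = remove_rigid_motion(sport_fo.surface_points_static, surface)
        d = depression_reformation(aligned, sport_fo.surface_points_static)
        pts = sport_fo.surface_points_static
        medial = (pts[:, 2] < -10) & (np.abs(pts[:, 0] - 95) < 30)
        assert d[medial].min() < -2.0


class TestFieldsAndPeaks:
    def test_zero_field_peaks(self):
        f = DeformationField(np.zeros((55, 101)))
        assert stance_peaks(f) == (0.0, 0.0)

    def test_single_cell_extreme(self):
        vals = np.zeros((55, 101))
        vals[13, 40] = -7.3
        assert stance_peaks(DeformationField(vals))[0] == pytest.approx(-7.3)

    def test_field_requires_101_samples(self):
        with pytest.raises(ParameterError):
            DeformationField(np.zeros((55, 100)))

    def test_injected_rigid_motion_leaves_field_unchanged(self, rng, sport_fo):
        """Deliberately rototranslating every frame changes the computed
        deformation field by less than 1e-6 mm."""
        static = sport_fo.surface_points_static
        n_frames = 40
        positions = np.tile(static, (n_frames, 1, 1))
        positions[:, 20, 1] -= np.linspace(0, 5, n_frames)  # growing dent
        moved = np.empty_like(positions)
        for i in range(n_frames):
            R = rotation_from_cardan_yxz(rng.uniform(-0.3, 0.3, 3))
            t = rng.uniform(-20, 20, 3)
            moved[i] = positions[i] @ R.T + t
        cycles = [StanceCycle(0, n_frames)]
        _, f_plain = deformation_field_from_positions(positions, static, cycles)
        _, f_moved = deformation_field_from_positions(moved, static, cycles)
        np.testing.assert_allclose(f_moved.values, f_plain.values, atol=1e-6)

    def test_mean_field_is_cellwise_mean_of_cycles(self, rng, sport_fo):
        static = sport_fo.surface_points_static
        positions = np.tile(static, (60, 1, 1))
        positions[:, 10, 1] -= rng.uniform(0, 3, 60)
        cycles = [StanceCycle(0, 30), StanceCycle(30, 60)]
        fields, mean_field = deformation_field_from_positions(positions, static, cycles)
        np.testing.assert_allclose(
            mean_field.values, (fields[0].values + fields[1].values) / 2, atol=1e-12
        )
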