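"""Trajectory construction, interpolation and label-algebra behaviour."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from seegbend.geometry import (
    AffineTransform,
    InvalidTrajectoryError,
    Trajectory,
    advance_point,
    apply_affine,
    compute_labels,
    interpolate_trajectory,
    rigid_trajectory,
    trajectory_mse,
    unit,
)


def random_unit_step_trajectory(rng, n_points=30, kink_sd_deg=3.0):
    """Random bent path with exact 1 mm steps (the implant model's output)."""
    pts = [np.zeros(3)]
    d = unit(rng.standard_normal(3))
    for _ in range(n_points - 1):
        axis = unit(np.cross(d, rng.standard_normal(3)))
        ang = np.deg2rad(rng.normal(0, kink_sd_deg))
        c, s = np.cos(ang), np.sin(ang)
        d = unit(d * c + np.cross(axis, d) * s)
        pts.append(pts[-1] + d)
    return Trajectory(np.asarray(pts), kind="implanted")


class TestInterpolation:
    def test_straight_line_unit_spacing(self):
        t = interpolate_trajectory([(0, 0, 0), (0, 0, 10)], spacing=1.0)
        assert len(t) == 11
        np.testing.assert_allclose(t.points[:, 2], np.arange(11), atol=1e-9)
        np.testing.assert_allclose(t.gaps(), 1.0, atol=1e-9)

    def test_curved_spacing_against_dense_arclength_oracle(self):
        controls = [(0, 0, 0), (0, 2, 5), (0, 2, 10)]
        t = interpolate_trajectory(controls, spacing=1.0)
        # independent oracle: dense PCHIP resampling at 10^4 samples
        pts = np.asarray(controls, float)
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        curve = PchipInterpolator(chord, pts, axis=0)
        dense = curve(np.linspace(0, chord[-1], 10_000))
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        total = arc[-1]
        assert len(t) == int(round(total)) + 1
        np.testing.assert_allclose(t.gaps(), 1.0, atol=0.05)
        # uniform among themselves much more tightly
        assert t.gaps().max() - t.gaps().min() < 0.01
        np.testing.assert_allclose(t.points[0], controls[0], atol=1e-9)
        np.testing.assert_allclose(t.points[-1], controls[-1], atol=1e-9)

    def test_already_unit_spaced_straight_polyline_is_identity(self):
        pts = np.column_stack([np.zeros(8), np.zeros(8), np.arange(8.0)])
        t = interpolate_trajectory(pts, spacing=1.0)
        np.testing.assert_allclose(t.points, pts, atol=1e-9)

    def test_duplicate_controls_dropped(self):
        t = interpolate_trajectory(
            [(0, 0, 0), (0, 0, 0), (0, 0, 5), (0, 0, 5), (0, 0, 10)]
        )
        assert len(t) == 11

    @pytest.mark.parametrize("controls", [[(1, 1, 1)], [(0, 0, 0), (0, 0, 0)]])
    def test_too_few_distinct_controls_rejected(self, controls):
        with pytest.raises(InvalidTrajectoryError):
            interpolate_trajectory(controls)


class TestRigidTrajectory:
    def test_axis_aligned(self):
        t = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=5, spacing=1.0)
        assert len(t) == 6
        np.testing.assert_allclose(t.points[-1], [0, 0, 5], atol=1e-12)

    def test_oblique_direction_unit_gaps(self):
        t = rigid_trajectory((1, 2, 3), np.ones(3) / np.sqrt(3), depth=3)
        assert len(t) == 4
        np.testing.assert_allclose(t.gaps(), 1.0, atol=1e-12)

    def test_labels_against_itself_vanish(self):
        t = rigid_trajectory((0, 0, 0), (1, 0, 0), depth=10)
        t = t.replace(kind="implanted")
        labels = compute_labels(t, t)
        np.testing.assert_allclose(labels.lu, 0.0, atol=1e-12)
        np.testing.assert_allclose(labels.gu, 0.0, atol=1e-12)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            rigid_trajectory((0, 0, 0), (0, 0, 0), depth=5)


class TestLabels:
    def test_hand_worked_example(self):
        traj = Trajectory([[0, 0, 0], [0, 0, 1], [0, 0.6, 1.8]],
                          kind="implanted")
        labels = compute_labels(traj)
        np.testing.assert_allclose(labels.v_hat[0], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(labels.x_p[0], [0, 0, 2], atol=1e-12)
        np.testing.assert_allclose(labels.lu[0], [0, 0.6, -0.2], atol=1e-12)
        np.testing.assert_allclose(labels.eb_hat[0], [0, 0.6, 0.8], atol=1e-12)

    def test_straight_trajectory_no_bending(self):
        t = rigid_trajectory((0, 0, 0), (0, 1, 0), depth=8).replace(
            kind="implanted"
        )
        labels = compute_labels(t)
        np.testing.assert_allclose(labels.lu, 0.0, atol=1e-12)
        np.testing.assert_allclose(labels.eb_hat, labels.v_hat, atol=1e-12)

    def test_identity_v_plus_lu_equals_eb_over_seeded_trajectories(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            traj = random_unit_step_trajectory(rng)
            labels = compute_labels(traj)
            np.testing.assert_allclose(labels.v_hat + labels.lu,
                                       labels.eb_hat, atol=1e-9)
            np.testing.assert_allclose(
                np.linalg.norm(labels.eb_hat, axis=1), 1.0, atol=1e-9
            )

    def test_lu_norm_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        traj = random_unit_step_trajectory(rng)
        base = np.linalg.norm(compute_labels(traj).lu, axis=1)
        for _ in range(20):
            # random rotation via QR, plus translation
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            m = np.eye(4)
            m[:3, :3] = q
            m[:3, 3] = rng.uniform(-50, 50, 3)
            moved = apply_affine(traj, AffineTransform(m))
            np.testing.assert_allclose(
                np.linalg.norm(compute_labels(moved).lu, axis=1), base,
                atol=1e-9,
            )

    def test_coincident_points_rejected(self):
        with pytest.raises(InvalidTrajectoryError):
            Trajectory([[0, 0, 0], [0, 0, 0], [0, 0, 1]])

    def test_rigid_too_short_for_gu(self):
        impl = random_unit_step_trajectory(np.random.default_rng(0), 20)
        short = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=5)
        with pytest.raises(InvalidTrajectoryError):
            compute_labels(impl, short)


class TestAdvancePoint:
    def test_inverse_of_worked_example(self):
        out = advance_point((0, 0, 1), (0, 0, 1), (0, 0.6, -0.2), "lu")
        np.testing.assert_allclose(out, [0, 0.6, 1.8], atol=1e-12)

    def test_zero_displacement_is_straight_step(self):
        out = advance_point((1, 2, 3), (1, 0, 0), (0, 0, 0), "lu")
        np.testing.assert_allclose(out, [2, 2, 3], atol=1e-12)

    def test_round_trip_with_compute_labels(self):
        rng = np.random.default_rng(11)
        traj = random_unit_step_trajectory(rng)
        labels = compute_labels(traj)
        for j, i in enumerate(labels.indices):
            for kind, lab in (("lu", labels.lu[j]), ("eb", labels.eb_hat[j])):
                nxt = advance_point(traj.points[i], labels.v_hat[j], lab, kind)
                np.testing.assert_allclose(nxt, traj.points[i + 1], atol=1e-9)

    def test_eb_renormalized_before_stepping(self):
        out = advance_point((0, 0, 0), (0, 0, 1), (0, 0, 5.0), "eb")
        np.testing.assert_allclose(out, [0, 0, 1], atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            advance_point((0, 0, 0), (0, 0, 2.0), (0, 0, 0), "lu")  # not unit
        with pytest.raises(ValueError):
            advance_point((0, 0, 0), (0, 0, 1), (0, 0, 0), "eb")  # zero eb


class TestAffine:
    def test_identity_and_translation(self):
        t = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=3)
        same = apply_affine(t, AffineTransform.identity())
        np.testing.assert_allclose(same.points, t.points, atol=1e-12)
        moved = apply_affine(t, AffineTransform.from_translation((1, 2, 3)))
        np.testing.assert_allclose(moved.points[0], [1, 2, 3], atol=1e-12)

    def test_random_affine_round_trip(self):
        rng = np.random.default_rng(0)
        t = rigid_trajectory((1, 1, 1), (0, 1, 0), depth=10)
        for _ in range(100):
            m = np.eye(4)
            m[:3, :3] = rng.standard_normal((3, 3)) + 3 * np.eye(3)
            m[:3, 3] = rng.uniform(-10, 10, 3)
            a = AffineTransform(m)
            back = apply_affine(apply_affine(t, a), a.inverse())
            np.testing.assert_allclose(back.points, t.points, atol=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((4, 4)))
        bad = np.eye(4)
        bad[3] = [0, 0, 1, 1]
        with pytest.raises(ValueError):
            AffineTransform(bad)


class TestTrajectoryMSE:
    def test_identical_is_zero(self):
        t = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=5)
        assert trajectory_mse(t, t) == 0.0

    def test_constant_lateral_offset(self):
        t = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=5)
        shifted = apply_affine(t, AffineTransform.from_translation((1, 0, 0)))
        assert trajectory_mse(shifted, t) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        a = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=5)
        b = rigid_trajectory((0, 0, 0), (0, 0, 1), depth=6)
        with pytest.raises(InvalidTrajectoryError):
            trajectory_mse(a, b)
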