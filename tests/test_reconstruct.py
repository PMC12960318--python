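"""Height solver, reference points, plane fit and the pose inverse."""

import numpy as np
import pytest

from maglevpiv.errors import (DegenerateGeometryError, InsufficientDataError,
                              MeasurementInconsistencyError)
from maglevpiv.markers import pair_and_assign
from maglevpiv.reconstruct import (blade_reference_point, fit_axis_and_center,
                                   reconstruct_pose, reconstruct_track,
                                   solve_channel_height)
from maglevpiv.synthetic import (MotionModel, default_motion_model, pose_at,
                                 project_channels)


def _forward_spacing(dx0, dy0, da, db, z):
    """Direct evaluation of the common-height spacing model."""
    return np.sqrt((da * z + dx0) ** 2 + (db * z + dy0) ** 2)


class TestHeightSolver:
    def test_orthogonal_configuration_example(self):
        """B = 0 case: spacing computed forward at z = 2.9 mm inverts
        back to exactly that height."""
        dx0, dy0, da, db = 0.0, 3.0, 0.2, 0.0
        d = _forward_spacing(dx0, dy0, da, db, 2.9)
        assert d == pytest.approx(np.sqrt(9.0 + 0.3364), abs=1e-12)
        sol = solve_channel_height(d, dx0, dy0, da, db)
        assert sol.z_mm == pytest.approx(2.9, abs=1e-12)

    def test_base_plane_spacing_gives_zero_height(self):
        dx0, dy0, da, db = 3.0, 1.0, 0.5, 0.3  # B > 0
        d0 = np.hypot(dx0, dy0)
        sol = solve_channel_height(d0, dx0, dy0, da, db)
        assert sol.z_mm == pytest.approx(0.0, abs=1e-12)

    def test_forward_substitution_reproduces_spacing(self, geom, rng):
        for _ in range(100):
            z = rng.uniform(0.0, 5.0)
            blade = int(rng.integers(1, 5))
            dx0, dy0, da, db = geom.deltas(blade)
            d = _forward_spacing(dx0, dy0, da, db, z)
            sol = solve_channel_height(d, dx0, dy0, da, db, blade=blade)
            assert _forward_spacing(dx0, dy0, da, db, sol.z_mm) == pytest.approx(
                d, abs=1e-10)
            assert sol.z_mm == pytest.approx(z, abs=1e-9)

    def test_ambiguous_roots_resolved_by_height_range(self, geom):
        """The default geometry has B < 0: both roots are positive and the
        physical range must pick the lower one."""
        dx0, dy0, da, db = geom.deltas(1)
        d = _forward_spacing(dx0, dy0, da, db, 2.9)
        sol = solve_channel_height(d, dx0, dy0, da, db)
        assert sol.z_mm == pytest.approx(2.9, abs=1e-9)
        assert sol.root_used == "alternate"

    def test_discriminant_below_tolerance_rejected(self):
        # spacing smaller than the geometric minimum of the model
        dx0, dy0, da, db = 0.0, 3.0, 0.2, 0.0
        with pytest.raises(MeasurementInconsistencyError, match="discriminant"):
            solve_channel_height(2.0, dx0, dy0, da, db, tol=1e-6)

    def test_slightly_negative_discriminant_clamped(self):
        dx0, dy0, da, db = 0.0, 3.0, 0.2, 0.0
        d_min = 3.0  # minimum of the model over z >= 0 is at z = 0
        sol = solve_channel_height(d_min - 1e-9, dx0, dy0, da, db, tol=1e-4)
        assert sol.clamped
        assert sol.z_mm >= 0.0

    def test_degenerate_slopes_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            solve_channel_height(3.0, 1.0, 1.0, 0.0, 0.0)

    def test_height_round_trip_against_exact_projection(self, geom, plane):
        """Closed-form heights vs the exact intersection heights of the
        forward model: the equal-height approximation costs up to
        ~28 um at the fixture's 1.1 degree peak tilt."""
        from maglevpiv.geometry import pose_matrix

        worst = 0.0
        model = default_motion_model()
        for alpha in np.arange(0.0, 360.0, 18.0):
            pose = pose_at(model, alpha)
            m = pose_matrix(pose)
            obs = {(o.blade, o.channel): o for o in
                   project_channels(pose, geom, plane)}
            for blade in (1, 2, 3, 4):
                o_in, o_out = obs[(blade, "in")], obs[(blade, "out")]
                d = np.hypot(o_in.x_mm - o_out.x_mm, o_in.y_mm - o_out.y_mm)
                sol = solve_channel_height(d, *geom.deltas(blade), blade=blade)
                p0, u = geom.channel_line(blade, "in")
                z_true = (plane.z_mm - (pose.center + m @ p0)[2]) / (m @ u)[2]
                worst = max(worst, abs(sol.z_mm - z_true))
        assert worst < 0.030

    def test_rejections_monotone_in_noise(self, geom, rng):
        """More marker noise can only increase the number of rejected
        (inconsistent) observations."""
        dx0, dy0, da, db = geom.deltas(1)
        d_true = _forward_spacing(dx0, dy0, da, db, 2.9)
        counts = []
        for sigma in (0.01, 0.1, 0.4):
            rejected = 0
            draws = rng.normal(0.0, 1.0, 400)
            for eps in draws:
                try:
                    solve_channel_height(d_true + sigma * eps, dx0, dy0, da, db)
                except MeasurementInconsistencyError:
                    rejected += 1
            counts.append(rejected)
        assert counts == sorted(counts)


class TestReferencePoint:
    def test_vertical_channel_straight_drop(self):
        p = blade_reference_point(np.array([10.0, 2.0]), -2.25, 2.9, 123.0,
                                  a_in=0.0, b_in=0.0)
        assert np.allclose(p, [10.0, 2.0, -2.25 - 2.9])

    def test_zero_alpha_no_rotation(self):
        p = blade_reference_point(np.array([10.0, 0.0]), -2.25, 2.0, 0.0,
                                  a_in=0.2, b_in=0.05)
        assert np.allclose(p, [10.0 - 0.4, -0.1, -4.25])

    def test_z_component_is_laser_minus_height(self):
        p = blade_reference_point(np.array([3.0, 4.0]), -2.25, 3.1, 211.0,
                                  a_in=0.2, b_in=0.05)
        assert p[2] == pytest.approx(-2.25 - 3.1)


class TestAxisCenterFit:
    def test_three_level_points_give_vertical_axis(self):
        pts = {1: np.array([10.0, 0.0, -5.0]), 2: np.array([0.0, 10.0, -5.0]),
               3: np.array([-10.0, 0.0, -5.0])}
        axis, center, residual = fit_axis_and_center(pts)
        assert np.allclose(axis, [0, 0, 1], atol=1e-12)
        assert residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(center, [0, 0, -5.0])

    def test_four_points_on_tilted_plane_recover_polar_angle(self):
        """Constructed-plane oracle: reference points placed on a plane
        tilted by 0.65 degrees yield that polar angle to 1e-9 deg."""
        from maglevpiv.geometry import RotationSpec, rotation_matrix, tilt_axis

        r = rotation_matrix(RotationSpec(tilt_axis(273.0), 0.65))
        pts = {n: r @ np.array([11.5 * np.cos(np.deg2rad(90 * (n - 1))),
                                11.5 * np.sin(np.deg2rad(90 * (n - 1))), 0.0])
               for n in (1, 2, 3, 4)}
        axis, center, residual = fit_axis_and_center(pts)
        theta = np.rad2deg(np.arccos(np.clip(axis[2], -1, 1)))
        assert theta == pytest.approx(0.65, abs=1e-9)
        assert residual < 1e-12
        assert np.allclose(center, 0.0, atol=1e-12)

    def test_axis_error_under_10um_noise(self, rng):
        """Monte-Carlo: 10 um Gaussian jitter on four points at fixture
        radii keeps the median axis error below 0.05 degrees."""
        base = {n: np.array([11.5 * np.cos(np.deg2rad(90 * (n - 1))),
                             11.5 * np.sin(np.deg2rad(90 * (n - 1))), 0.0])
                for n in (1, 2, 3, 4)}
        errors = []
        for _ in range(1000):
            pts = {n: p + rng.normal(0, 0.010, 3) for n, p in base.items()}
            axis, _, _ = fit_axis_and_center(pts)
            errors.append(np.rad2deg(np.arccos(np.clip(axis[2], -1, 1))))
        assert np.median(errors) < 0.05

    def test_collinear_and_insufficient_rejected(self):
        line = {n: np.array([float(n), 0.0, 0.0]) for n in (1, 2, 3)}
        with pytest.raises(DegenerateGeometryError):
            fit_axis_and_center(line)
        with pytest.raises(InsufficientDataError):
            fit_axis_and_center({1: np.zeros(3), 2: np.ones(3)})


def _pairing_for(pose, geom, plane, drop_blade=None):
    obs = project_channels(pose, geom, plane)
    if drop_blade is not None:
        obs = [o for o in obs if o.blade != drop_blade]
    pts = np.array([[o.x_mm, o.y_mm] for o in obs])
    return pair_and_assign(pts, np.zeros(2), geom,
                           expected_alpha_deg=pose.alpha_deg,
                           frame_index=pose.frame_index)


class TestReconstructPose:
    def test_ideal_rotation_recovered_sharply(self, geom, plane):
        pose_t = pose_at(MotionModel(), 42.0)
        pairing = _pairing_for(pose_t, geom, plane)
        rec, diag = reconstruct_pose(pairing, geom, plane, alpha0_deg=42.0)
        assert np.linalg.norm(rec.center - pose_t.center) < 1e-3
        assert rec.theta_deg < 0.01
        assert diag.converged and diag.n_blades_used == 4

    def test_three_blade_frame_still_reconstructs(self, geom, plane):
        pose_t = pose_at(default_motion_model(), 42.0)
        pairing = _pairing_for(pose_t, geom, plane, drop_blade=4)
        rec, diag = reconstruct_pose(pairing, geom, plane, alpha0_deg=42.0)
        assert diag.n_blades_used == 3
        assert np.linalg.norm(rec.center[:2] - pose_t.center[:2]) < 0.05

    def test_too_few_blades_rejected(self, geom, plane):
        pose_t = pose_at(MotionModel(), 10.0)
        pairing = _pairing_for(pose_t, geom, plane, drop_blade=1)
        del pairing.pairs[2]
        with pytest.raises(InsufficientDataError):
            reconstruct_pose(pairing, geom, plane, alpha0_deg=10.0)


class TestForwardInverseConsistency:
    """Round trips over one revolution of the full fixture motion."""

    @pytest.fixture(scope="class")
    def revolution(self, geom, plane):
        model = default_motion_model()
        step = 360.0 * model.rotation_rate_rpm / (60.0 * 10000.0)
        poses = [pose_at(model, k * 6.0 * step, frame_index=k)
                 for k in range(43)]  # every 6th frame of a revolution
        pairings = [_pairing_for(p, geom, plane) for p in poses]
        return poses, pairings, step * 6.0

    @staticmethod
    def _errors(rec, truth):
        ce = [np.linalg.norm(r.center - t.center) for r, t in zip(rec, truth)]
        ae = [np.rad2deg(np.arccos(np.clip(r.axis @ t.axis, -1, 1)))
              for r, t in zip(rec, truth)]
        de = [min(abs(r.alpha_deg - t.alpha_deg),
                  360 - abs(r.alpha_deg - t.alpha_deg))
              for r, t in zip(rec, truth)]
        return np.array(ce), np.array(ae), np.array(de)

    def test_exact_solver_machine_precision(self, geom, plane, revolution):
        poses, pairings, step = revolution
        rec, _ = reconstruct_track(pairings, geom, plane, 0.0, step, exact=True)
        ce, ae, de = self._errors(rec, poses)
        assert ce.max() < 1e-9
        assert ae.max() < 1e-9
        assert de.max() < 1e-9

    def test_closed_form_bounded_by_approximation_error(self, geom, plane,
                                                        revolution):
        """The equal-height closed form carries a first-order-in-tilt
        error: at the fixture's 1.1 degree peak tilt it stays within
        15 um on the centre, 0.15 deg on the axis and 0.001 deg on the
        blade angle (bounds frozen from the measured behaviour)."""
        poses, pairings, step = revolution
        rec, _ = reconstruct_track(pairings, geom, plane, 0.0, step,
                                   exact=False)
        ce, ae, de = self._errors(rec, poses)
        assert ce.max() < 0.015
        assert ae.max() < 0.15
        assert de.max() < 0.001

    def test_plain_backprojection_strictly_worse(self, geom, plane):
        """Dropping the tilt factor in the back-projection (the fully
        approximated reference-point formula) costs about 50 um of
        centre error at 1 degree of tilt."""
        pose_t = pose_at(default_motion_model(), 37.0)
        pairing = _pairing_for(pose_t, geom, plane)
        rec_plain, _ = reconstruct_pose(pairing, geom, plane, 37.0,
                                        tilt_correction=False)
        rec_corr, _ = reconstruct_pose(pairing, geom, plane, 37.0)
        err_plain = np.linalg.norm(rec_plain.center - pose_t.center)
        err_corr = np.linalg.norm(rec_corr.center - pose_t.center)
        assert err_corr < err_plain
        assert 0.02 < err_plain < 0.10
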