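"""Sphere fitting, calibration and globographic angles."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from shoulder_torque import synthetic_data as sd
from shoulder_torque.robot_model import forward_kinematics
from shoulder_torque.shoulder_kinematics import (CalibrationRecord,
                                                DegenerateGeometryError,
                                                calibrate, fit_sphere,
                                                globographic_angles,
                                                project_to_sphere,
                                                shoulder_transform)
from shoulder_torque.transforms import RigidTransform, rotation_about


def sphere_points(center, radius, n, rng, cap=None, noise=0.0):
    """Random points on a sphere (optionally a polar cap of half-angle `cap`)."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if cap is not None:
        # squeeze directions into a cap about +z
        u[:, 2] = np.abs(u[:, 2])
        w = np.cos(cap)
        u[:, 2] = w + (1 - w) * u[:, 2]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = center + radius * u
    if noise > 0:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return pts


def geometric_sphere_fit(points, x0):
    """Independent oracle: iterative minimization of the true geometric
    point-to-surface distance."""

    def resid(x):
        return np.linalg.norm(points - x[:3], axis=1) - x[3]

    return least_squares(resid, x0).x


class TestFitSphere:
    def test_exact_on_noiseless_points(self, rng):
        center = np.array([0.10, -0.20, 0.30])
        pts = sphere_points(center, 0.25, 100, rng)
        fit = fit_sphere(pts)
        assert np.abs(fit.center - center).max() < 1e-9
        assert abs(fit.radius - 0.25) < 1e-9
        assert fit.rms_residual < 1e-9

    def test_noisy_cap_against_geometric_oracle(self, rng):
        # 1 mm isotropic noise on a spherical cap, n = 500: center within
        # 5 mm of truth and close to the independent iterative geometric fit
        center = np.array([0.10, -0.20, 0.30])
        pts = sphere_points(center, 0.25, 500, rng, cap=np.deg2rad(60), noise=1e-3)
        fit = fit_sphere(pts)
        assert np.linalg.norm(fit.center - center) < 5e-3
        oracle = geometric_sphere_fit(pts, np.array([*center, 0.25]))
        assert np.linalg.norm(fit.center - oracle[:3]) < 1e-3
        assert abs(fit.radius - oracle[3]) < 1e-3

    def test_center_error_decreases_with_n(self, rng):
        center = np.zeros(3)
        errs = {}
        for n in (50, 500, 5000):
            draws = [
                np.linalg.norm(
                    fit_sphere(sphere_points(center, 0.25, n, rng,
                                             cap=np.deg2rad(70), noise=1e-3)).center
                    - center)
                for _ in range(5)
            ]
            errs[n] = np.mean(draws)
        assert errs[50] > errs[500] > errs[5000]

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.eye(3))


class TestProjectToSphere:
    def test_point_on_sphere_is_fixed(self, rng):
        fit = fit_sphere(sphere_points(np.array([1.0, 2.0, 3.0]), 0.5, 50, rng))
        p = fit.center + np.array([0.5, 0.0, 0.0])
        assert np.allclose(project_to_sphere(p, fit), p, atol=1e-9)

    def test_collinear_scaling(self, rng):
        fit = fit_sphere(sphere_points(np.zeros(3), 0.5, 50, rng))
        p = fit.center + np.array([1.0, 0.0, 0.0])
        assert np.allclose(project_to_sphere(p, fit), fit.center + [0.5, 0, 0], atol=1e-9)

    def test_center_rejected(self, rng):
        fit = fit_sphere(sphere_points(np.zeros(3), 0.5, 50, rng))
        with pytest.raises(DegenerateGeometryError):
            project_to_sphere(fit.center, fit)


class TestCalibrate:
    def test_round_trip_with_generator(self, scene):
        # the synthetic scene knows its true flange-to-shoulder transform
        calib = calibrate(scene.reference_axes, scene.radius,
                          scene.elbow_in_flange, scene.robot)
        truth = scene.flange_ref.inverse() @ RigidTransform(np.eye(3), scene.center)
        assert calib.flange_to_shoulder.isclose(truth, atol=1e-9)

    def test_identity_when_frames_coincide(self, robot):
        # place the elbow straight below the flange at exactly the radius:
        # shoulder frame coincides with a world-aligned flange frame
        q_ref = np.zeros(7)
        T = forward_kinematics(q_ref, robot)
        assert np.allclose(T.rotation, np.eye(3))
        radius = 0.3
        # elbow straight below the flange origin at the radius: the shoulder
        # center lands exactly on the (world-aligned) flange origin
        elbow_in_flange = np.array([0.0, 0.0, -radius])
        calib = calibrate(q_ref, radius, elbow_in_flange, robot)
        assert calib.flange_to_shoulder.isclose(RigidTransform.identity(), atol=1e-12)

    def test_reference_pose_rotation_is_identity(self, scene):
        calib = scene.calibration
        T_s = shoulder_transform(scene.reference_axes, calib, scene.robot)
        assert np.allclose(T_s.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T_s.translation, scene.center, atol=1e-9)

    def test_nonpositive_radius_rejected(self, scene):
        with pytest.raises(ValueError):
            calibrate(scene.reference_axes, 0.0, scene.elbow_in_flange, scene.robot)

    def test_json_round_trip(self, tmp_path, scene):
        calib = scene.calibration
        path = tmp_path / "calib.json"
        calib.save(path)
        loaded = CalibrationRecord.load(path)
        assert loaded.flange_to_shoulder.isclose(calib.flange_to_shoulder, atol=1e-15)
        assert np.allclose(loaded.elbow_in_flange, calib.elbow_in_flange)


class TestShoulderTransform:
    def test_translation_constant_along_rigid_rotation(self, scene, field, orthosis, robot_scene):
        # a pure rotation about the fixed center keeps T_s's origin put
        log, truth = robot_scene
        calib = scene.calibration
        for i in range(0, len(truth.axes), 7):
            T_s = shoulder_transform(truth.axes[i], calib, scene.robot)
            assert np.allclose(T_s.translation, scene.center, atol=1e-6)

    def test_inverse_recovers_flange_pose(self, scene):
        calib = scene.calibration
        q = scene.reference_axes
        T_s = shoulder_transform(q, calib, scene.robot)
        T_F = T_s @ calib.flange_to_shoulder.inverse()
        assert T_F.isclose(forward_kinematics(q, scene.robot), atol=1e-12)


class TestGlobographicAngles:
    def _unit_fit(self, rng):
        return fit_sphere(sphere_points(np.array([0.3, -0.1, 0.9]), 0.3, 60, rng))

    def test_pole_is_degenerate(self, rng):
        fit = self._unit_fit(rng)
        p = globographic_angles(fit.center + [0, 0, -fit.radius], fit)
        assert p.degenerate
        # arccos near its endpoint has sqrt-of-eps precision
        assert p.elevation == pytest.approx(0.0, abs=1e-6)
        assert p.plane_of_elevation == 0.0

    def test_coronal_abduction(self, rng):
        fit = self._unit_fit(rng)
        p = globographic_angles(fit.center + [fit.radius, 0, 0], fit)
        assert not p.degenerate
        assert p.plane_of_elevation == pytest.approx(0.0, abs=1e-12)
        assert p.elevation == pytest.approx(np.pi / 2, abs=1e-12)

    def test_round_trip_away_from_pole(self, rng):
        fit = self._unit_fit(rng)
        for plane, elev in [(0.3, 1.1), (-2.0, 0.4), (3.0, 2.8)]:
            u = np.array([np.sin(elev) * np.cos(plane),
                          np.sin(elev) * np.sin(plane), -np.cos(elev)])
            p = globographic_angles(fit.center + 2.0 * u, fit)
            assert p.plane_of_elevation == pytest.approx(plane, abs=1e-9)
            assert p.elevation == pytest.approx(elev, abs=1e-9)
            assert np.allclose(p.elbow_on_sphere, fit.center + fit.radius * u, atol=1e-9)

    def test_invariant_to_axial_rotation(self, rng):
        # rotating the scene about the center-to-elbow axis leaves the
        # elbow, hence the angles, unchanged: axial rotation is excluded
        fit = self._unit_fit(rng)
        elbow = fit.center + np.array([0.2, 0.1, -0.15])
        axis = (elbow - fit.center) / np.linalg.norm(elbow - fit.center)
        R = rotation_about(axis, 1.234)
        rotated = fit.center + R @ (elbow - fit.center)
        p0 = globographic_angles(elbow, fit)
        p1 = globographic_angles(rotated, fit)
        assert p0.plane_of_elevation == pytest.approx(p1.plane_of_elevation)
        assert p0.elevation == pytest.approx(p1.elevation)


def test_former_part_fits_better_under_center_drift(scene):
    # end-stage center translation inflates the full-trajectory residual:
    # fitting on the former part of the run is the right call
    traj = sd.generate_trajectory(sd.TrajectorySpec(n_samples=200, seed=5))
    elbows = sd.drifted_elbow_points(traj, scene, drift=0.03, onset=0.7)
    former = fit_sphere(elbows[: int(0.7 * len(elbows))])
    full = fit_sphere(elbows)
    assert former.rms_residual < full.rms_residual
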