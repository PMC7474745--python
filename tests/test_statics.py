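"""Moving-average filtering, orthosis compensation and passive torque."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shoulder_torque.robot_model import Wrench
from shoulder_torque.statics import (GRAVITY, ComparisonError, OrthosisParams,
                                     compensate_orthosis, moving_average,
                                     orthosis_gravity_wrench, passive_torque,
                                     repeatability_check)
from shoulder_torque.transforms import RigidTransform, rotation_about


class TestMovingAverage:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(-100, 100), st.integers(1, 50), st.integers(0, 12))
    def test_constant_series_unchanged(self, c, n, half_w):
        out = moving_average(np.full(n, c), 2 * half_w + 1)
        assert np.allclose(out, c)

    def test_impulse_plateau(self):
        w = 5
        x = np.zeros(41)
        x[20] = 1.0
        out = moving_average(x, w)
        assert np.allclose(out[18:23], 1.0 / w)
        assert np.allclose(out[:16], 0.0) and np.allclose(out[25:], 0.0)

    def test_sinusoid_gain_matches_dirichlet_kernel(self):
        # interior gain of a length-w mean on a sinusoid at normalized
        # frequency f is |sin(pi f w) / (w sin(pi f))|
        f, w, n = 0.05, 11, 400
        x = np.sin(2 * np.pi * f * np.arange(n))
        out = moving_average(x, w)
        gain = abs(np.sin(np.pi * f * w) / (w * np.sin(np.pi * f)))
        interior = slice(w, n - w)
        assert np.abs(out[interior] - gain * x[interior]).max() < 1e-9

    def test_output_length_and_vector_series(self):
        x = np.arange(30, dtype=float).reshape(10, 3)
        out = moving_average(x, 5)
        assert out.shape == x.shape

    @pytest.mark.parametrize("window", [0, -3, 2, 8])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), window)


class TestCompensateOrthosis:
    def test_zero_mass_is_identity(self):
        w = Wrench([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        pose = RigidTransform.from_rotvec([0.3, 0.1, -0.2], [0.5, 0, 0.4])
        out = compensate_orthosis(w, pose, OrthosisParams(0.0, np.zeros(3)))
        assert np.allclose(out.as_vector(), w.as_vector())

    def test_pure_orthosis_scene_compensates_to_zero(self):
        # a log containing only the orthosis hanging statically
        orth = OrthosisParams(0.8, [0.02, -0.01, 0.05])
        pose = RigidTransform.from_rotvec([0.2, -0.4, 0.1], [0.4, 0.1, 0.5])
        measured = orthosis_gravity_wrench(pose, orth)
        out = compensate_orthosis(measured, pose, orth)
        assert np.abs(out.as_vector()).max() < 1e-9

    def test_moment_change_is_gravity_moment(self):
        orth = OrthosisParams(1.3, [0.0, 0.0, 0.06])
        pose = RigidTransform.from_rotvec([0.0, 0.9, 0.0], [0.3, 0.0, 0.6])
        w = Wrench([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        out = compensate_orthosis(w, pose, orth)
        fg = np.array([0.0, 0.0, -orth.mass * GRAVITY])
        expected = -np.cross(pose.rotate(orth.com_in_flange), fg)
        assert np.allclose(out.moment, expected, atol=1e-12)
        assert np.allclose(out.force, -fg, atol=1e-12)


class TestPassiveTorque:
    def test_zero_wrench_zero_torque(self):
        pose = RigidTransform.identity()
        mp = passive_torque(Wrench(np.zeros(3), np.zeros(3)), pose, [0.1, 0.2, 0.3])
        assert np.allclose(mp, 0.0)

    def test_recovers_generated_field(self, flange_scene, scene, orthosis):
        # equilibrium-constructed round trip: the statics stage must return
        # the generator's M_s + M_G at every sample
        log, truth = flange_scene
        for i in range(len(truth.t)):
            w = Wrench(truth.wrench_env[i, :3], truth.wrench_env[i, 3:])
            w = compensate_orthosis(w, truth.flange_poses[i], orthosis)
            mp = passive_torque(w, truth.flange_poses[i], truth.center)
            assert np.abs(mp - truth.torque[i]).max() < 1e-9

    def test_force_balance_companion(self, flange_scene, orthosis, field):
        # F_s + F_R + G = 0 with the generator's convention F_s = 0, so the
        # compensated limb wrench force must equal limb weight
        log, truth = flange_scene
        G = np.array([0.0, 0.0, -field.limb.mass * GRAVITY])
        for i in range(0, len(truth.t), 7):
            w = Wrench(truth.wrench_env[i, :3], truth.wrench_env[i, 3:])
            w = compensate_orthosis(w, truth.flange_poses[i], orthosis)
            F_R = -w.force           # robot-on-limb assist force
            F_s = -F_R - G
            assert np.abs(F_s).max() < 1e-9

    def test_frame_covariance(self, rng):
        # rotating the whole scene rotates M_P by the same rotation
        R = rotation_about(rng.normal(size=3), 0.8)
        pose = RigidTransform.from_rotvec([0.1, 0.2, 0.3], [0.4, -0.2, 0.5])
        w = Wrench(rng.normal(size=3), rng.normal(size=3))
        center = np.array([0.1, 0.0, 0.6])
        mp = passive_torque(w, pose, center)
        pose_r = RigidTransform(R, np.zeros(3)) @ pose
        w_r = Wrench(R @ w.force, R @ w.moment)
        mp_r = passive_torque(w_r, pose_r, R @ center)
        assert np.allclose(mp_r, R @ mp, atol=1e-12)


def _run_frame(elev, torque):
    t = np.asarray(torque, dtype=float)
    return pd.DataFrame({"elevation": elev, "mx": t[:, 0], "my": t[:, 1], "mz": t[:, 2]})


class TestRepeatability:
    def test_identical_runs_pass_with_zero_metric(self, rng):
        elev = np.linspace(0.2, 2.0, 50)
        torque = rng.normal(size=(50, 3))
        run = _run_frame(elev, torque)
        res = repeatability_check(run, run.copy())
        assert res.passed and res.rms_fraction == 0.0

    def test_large_offset_fails(self, rng):
        elev = np.linspace(0.2, 2.0, 50)
        torque = rng.normal(size=(50, 3))
        res = repeatability_check(_run_frame(elev, torque),
                                  _run_frame(elev, torque + 10.0), tol=0.1)
        assert not res.passed

    def test_metric_symmetric(self, rng):
        elev = np.linspace(0.2, 2.0, 50)
        a = _run_frame(elev, rng.normal(size=(50, 3)))
        b = _run_frame(elev, rng.normal(size=(50, 3)))
        assert repeatability_check(a, b).rms_fraction == pytest.approx(
            repeatability_check(b, a).rms_fraction)

    def test_disjoint_ranges_rejected(self, rng):
        a = _run_frame(np.linspace(0.1, 0.5, 20), rng.normal(size=(20, 3)))
        b = _run_frame(np.linspace(1.0, 1.5, 20), rng.normal(size=(20, 3)))
        with pytest.raises(ComparisonError):
            repeatability_check(a, b)
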