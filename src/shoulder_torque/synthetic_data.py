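"""Ground-truth scenes and DataRecorder-style logs for the whole pipeline.

The generator emulates the measurement setting: a rigid upper limb on a
ball-and-socket joint with a fixed rotation center, carrying a parametric
passive torque field (limb gravity about the center plus a nonlinear
elastic resistance that is zero at the neutral hanging posture and rises
steeply toward the range-of-motion limit), dragged quasi-statically along
abduction trajectories with a small unconscious "secondary movement" in
the plane of elevation.  Every rendered sample satisfies the quasi-static
force and moment balances by construction, so each pipeline stage can be
validated by round trip without hardware.

Two rendering levels exist: flange-level logs (pose + wrench time series)
exercise the statics stages directly; robot-level logs (axis angles +
external joint torques, via damped least-squares inverse kinematics and
the virtual-work map tau_e = J^T f) exercise the full chain.

Generator convention for the statically over-determined limb: the robot
carries the full limb weight (shoulder reaction force zero) and supplies
the full moment balance at the flange.  The pipeline only ever uses the
moment of the flange wrench about the center, which is invariant to this
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .robot_model import RobotParams, default_robot, forward_kinematics, jacobian
from .shoulder_kinematics import CalibrationRecord, calibrate
from .statics import GRAVITY, LimbParams, OrthosisParams, orthosis_gravity_wrench
from .robot_model import Wrench
from .transforms import RigidTransform, rotation_about

__all__ = [
    "TorqueFieldParams",
    "TrajectorySpec",
    "Scene",
    "SceneTruth",
    "UnreachablePoseError",
    "torque_field",
    "generate_trajectory",
    "render_flange_log",
    "numeric_ik",
    "render_robot_log",
    "default_scene",
    "default_field",
    "default_orthosis",
]

_DOWN = np.array([0.0, 0.0, -1.0])


class UnreachablePoseError(RuntimeError):
    """Inverse kinematics failed to converge to the target pose."""


@dataclass(frozen=True)
class TorqueFieldParams:
    """Parametric passive torque field M_P(posture) = gravity + elastic.

    The elastic resistance about the elevation axis is a progressive
    stiffening profile

    ``g(theta) = k_linear theta + k_cubic theta^3
    + edge_mag (exp((theta - elev_limit)/edge_scale) - exp(-elev_limit/edge_scale))
    + ripple_mag sin(2 pi (theta - ripple_phase)/ripple_period) (1 - exp(-theta/ripple_onset))``

    zero at the neutral hanging posture and steep near the range-of-motion
    limit, as passive joint torque-angle curves are.  The bounded ripple
    term models the undulation that sequential engagement of
    capsuloligamentous structures (and orthosis-tissue interaction)
    superposes on the progressive stiffening; its onset envelope keeps the
    resistance zero at neutral.  The resistance about the vertical is a
    linear restoring term ``plane_stiffness * phi`` plus its own
    engagement undulation of magnitude ``vertical_ripple_mag`` sharing the
    same period and envelope.

    Units: k_linear N·m/rad, k_cubic N·m/rad^3, edge_mag and ripple_mag
    N·m, edge_scale / ripple_period / ripple_phase / ripple_onset rad,
    plane_stiffness N·m/rad, limits rad.
    """

    limb: LimbParams = field(default_factory=lambda: LimbParams(mass=3.5, com_offset=0.28))
    k_linear: float = 0.5
    k_cubic: float = 0.8
    edge_mag: float = 4.0
    edge_scale: float = 0.14
    elev_limit: float = np.deg2rad(125.0)
    ripple_mag: float = 1.0
    ripple_period: float = np.deg2rad(25.0)
    ripple_phase: float = np.deg2rad(10.0)
    ripple_onset: float = 0.2
    vertical_ripple_mag: float = 0.8
    plane_stiffness: float = 2.0
    plane_limit: float = np.deg2rad(90.0)


@dataclass(frozen=True)
class TrajectorySpec:
    """One passive abduction run: a monotone elevation ramp in a nominal
    plane of elevation, with seeded low-frequency secondary wander of the
    plane angle.  Sampled at ``sample_rate`` Hz."""

    plane_of_elevation: float = 0.0
    elevation_start: float = np.deg2rad(10.0)
    elevation_stop: float = np.deg2rad(120.0)
    secondary_amplitude: float = np.deg2rad(3.0)
    n_samples: int = 562
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elevation_stop > self.elevation_start:
            raise ValueError("elevation_stop must exceed elevation_start")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass(frozen=True)
class Scene:
    """Fixed geometry tying the limb to the robot: the reference axes pose
    (all shoulder angles zero), the elbow landmark in flange coordinates,
    the shoulder-to-elbow radius, and the derived world-frame quantities."""

    robot: RobotParams
    reference_axes: np.ndarray
    elbow_in_flange: np.ndarray
    radius: float
    center: np.ndarray          # shoulder rotation center, world
    flange_ref: RigidTransform  # flange pose at the reference posture

    @property
    def calibration(self) -> CalibrationRecord:
        return calibrate(self.reference_axes, self.radius, self.elbow_in_flange, self.robot)


def default_scene(robot: RobotParams | None = None) -> Scene:
    """Standard scene: elbow landmark 5 cm beyond the flange plate along
    its normal, upper-arm (shoulder-to-elbow) radius 0.30 m, reference pose
    a comfortable elbow-down configuration in front of the robot."""
    robot = robot or default_robot()
    # elbow-down pose ~0.55 m in front of the base at 0.55 m height, flange
    # plate facing down (the orthosis hangs beneath it)
    reference_axes = np.array([0.0, 2.0082, 0.0, -1.8335, 0.0, 2.9669, 0.0])
    elbow_in_flange = np.array([0.0, 0.0, 0.05])
    radius = 0.30
    T_ref = forward_kinematics(reference_axes, robot)
    center = T_ref.apply(elbow_in_flange) + radius * np.array([0.0, 0.0, 1.0])
    return Scene(robot=robot, reference_axes=reference_axes,
                 elbow_in_flange=elbow_in_flange, radius=radius,
                 center=center, flange_ref=T_ref)


def default_field() -> TorqueFieldParams:
    return TorqueFieldParams()


def default_orthosis() -> OrthosisParams:
    return OrthosisParams(mass=0.8, com_in_flange=np.array([0.0, 0.0, 0.04]))


# ------------------------------------------------------------------ field

def _arm_direction(plane: np.ndarray, elevation: np.ndarray) -> np.ndarray:
    """Unit direction shoulder-center -> elbow for globographic angles."""
    st, ct = np.sin(elevation), np.cos(elevation)
    return np.stack([st * np.cos(plane), st * np.sin(plane), -ct], axis=-1)


def _elevation_axis(plane: np.ndarray) -> np.ndarray:
    """World axis about which positive rotation raises the elevation."""
    return np.stack([np.sin(plane), -np.cos(plane), np.zeros_like(plane)], axis=-1)


def torque_field(params: TorqueFieldParams):
    """Return ``f(plane, elevation) -> M_P`` (N·m, world axes), vectorized.

    M_P is the sum of the limb gravity torque about the center and the
    elastic resistance; both vanish at the neutral hanging posture.
    """

    def f(plane, elevation):
        plane = np.asarray(plane, dtype=float)
        elevation = np.asarray(elevation, dtype=float)
        scalar = plane.ndim == 0
        plane, elevation = np.atleast_1d(plane), np.atleast_1d(elevation)
        u = _arm_direction(plane, elevation)
        g_vec = np.array([0.0, 0.0, -params.limb.mass * GRAVITY])
        m_gravity = np.cross(params.limb.com_offset * u, g_vec)
        th, s = elevation, params.edge_scale
        ripple = (np.sin(2 * np.pi * (th - params.ripple_phase) / params.ripple_period)
                  * (1.0 - np.exp(-th / params.ripple_onset)))
        g_el = (params.k_linear * th + params.k_cubic * th**3
                + params.edge_mag * (np.exp((th - params.elev_limit) / s)
                                     - np.exp(-params.elev_limit / s))
                + params.ripple_mag * ripple)
        m_elastic = -g_el[:, None] * _elevation_axis(plane)
        m_elastic[:, 2] += params.vertical_ripple_mag * ripple - params.plane_stiffness * plane
        out = m_gravity + m_elastic
        return out[0] if scalar else out

    return f


# -------------------------------------------------------------- trajectory

def generate_trajectory(spec: TrajectorySpec) -> pd.DataFrame:
    """Posture time series: columns ``t, plane, elevation`` (s, rad).

    Elevation ramps linearly (strictly increasing); the plane of elevation
    wanders around its nominal value as a seeded sum of low-frequency
    random-phase sinusoids scaled to the requested amplitude.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    elevation = np.linspace(spec.elevation_start, spec.elevation_stop, n)
    if spec.secondary_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        freqs = rng.uniform(0.05, 0.3, size=3)          # Hz, slow wander
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.5, 1.0, size=3)
        w = np.sum(amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0)
        w *= spec.secondary_amplitude / np.abs(w).max()
    else:
        w = np.zeros(n)
    return pd.DataFrame({"t": t, "plane": spec.plane_of_elevation + w, "elevation": elevation})


# ---------------------------------------------------------------- rendering

@dataclass
class SceneTruth:
    """Per-sample ground truth carried alongside a rendered log."""

    t: np.ndarray
    plane: np.ndarray
    elevation: np.ndarray
    flange_poses: list
    elbow_world: np.ndarray
    torque: np.ndarray          # true M_P, world axes
    wrench_env: np.ndarray      # limb+orthosis action on the flange, (n, 6)
    center: np.ndarray
    radius: float
    tau_e: np.ndarray | None = None
    axes: np.ndarray | None = None

    def torque_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "plane": self.plane, "elevation": self.elevation,
            "mx": self.torque[:, 0], "my": self.torque[:, 1], "mz": self.torque[:, 2],
        })


def _limb_motion(traj: pd.DataFrame, scene: Scene):
    """Rigid limb poses along a trajectory.

    The limb rotates about the fixed center by the minimal rotation taking
    the reference (vertical, hanging) arm direction to the commanded one —
    no axial roll, matching the protocol's no-upper-arm-rotation
    instruction.  Returns flange poses and elbow world points.
    """
    plane = traj["plane"].to_numpy()
    elevation = traj["elevation"].to_numpy()
    u = _arm_direction(plane, elevation)
    poses, elbows = [], np.empty((len(traj), 3))
    p0 = scene.flange_ref.translation
    R0 = scene.flange_ref.rotation
    for i in range(len(traj)):
        axis = np.cross(_DOWN, u[i])
        norm = np.linalg.norm(axis)
        angle = np.arccos(np.clip(_DOWN @ u[i], -1.0, 1.0))
        if norm < 1e-12:
            R_l = np.eye(3)
        else:
            R_l = rotation_about(axis / norm, angle)
        pose = RigidTransform(R_l @ R0, scene.center + R_l @ (p0 - scene.center))
        poses.append(pose)
        elbows[i] = pose.apply(scene.elbow_in_flange)
    return poses, elbows


def _equilibrium_wrenches(poses, plane, elevation, field_params: TorqueFieldParams,
                          orthosis: OrthosisParams, center: np.ndarray):
    """Ground-truth M_P and the environment wrench on the flange for each
    sample, from the quasi-static balance (robot carries the limb weight
    and supplies the full moment balance)."""
    f = torque_field(field_params)
    m_p = f(plane, elevation)
    n = len(poses)
    wrench_env = np.empty((n, 6))
    for i in range(n):
        F_R = np.array([0.0, 0.0, field_params.limb.mass * GRAVITY])   # robot on limb
        # moment of the assist force about the shoulder center
        m_fr = np.cross(poses[i].translation - center, F_R)
        M_R = -(m_p[i] + m_fr)
        f_orth = orthosis_gravity_wrench(poses[i], orthosis)
        wrench_env[i, :3] = -F_R + f_orth.force
        wrench_env[i, 3:] = -M_R + f_orth.moment
    return m_p, wrench_env


def render_flange_log(traj: pd.DataFrame, field_params: TorqueFieldParams, scene: Scene,
                      orthosis: OrthosisParams, noise_sigma: float = 0.0,
                      seed: int | None = None):
    """Flange-level log: pose (12 numbers, row-major R then p) + measured
    environment wrench, plus the :class:`SceneTruth` sidecar.

    ``noise_sigma`` adds iid Gaussian noise (N and N·m) to the wrench
    channels, emulating sensor noise.
    """
    poses, elbows = _limb_motion(traj, scene)
    plane = traj["plane"].to_numpy()
    elevation = traj["elevation"].to_numpy()
    m_p, wrench_env = _equilibrium_wrenches(poses, plane, elevation, field_params,
                                            orthosis, scene.center)
    measured = wrench_env.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        measured += rng.normal(0.0, noise_sigma, size=measured.shape)
    t = traj["t"].to_numpy()
    cols = {"t": t}
    names = ["r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33", "px", "py", "pz"]
    flat = np.array([np.concatenate([p.rotation.ravel(), p.translation]) for p in poses])
    for j, name in enumerate(names):
        cols[name] = flat[:, j]
    for j, name in enumerate(["fx", "fy", "fz", "mx", "my", "mz"]):
        cols[name] = measured[:, j]
    log = pd.DataFrame(cols)
    truth = SceneTruth(t=t, plane=plane, elevation=elevation, flange_poses=poses,
                       elbow_world=elbows, torque=m_p, wrench_env=wrench_env,
                       center=scene.center.copy(), radius=scene.radius)
    return log, truth


# ---------------------------------------------------------------------- IK

def numeric_ik(target: RigidTransform, q0, params: RobotParams,
               tol: float = 1e-8, max_iter: int = 200, damping: float = 1e-4) -> np.ndarray:
    """Damped least-squares inverse kinematics.

    Iterates ``dq = J^T (J J^T + lambda^2 I)^{-1} e`` on the mixed
    position (m) / orientation (rad, rotation-vector) error until its norm
    drops below ``tol``.  Starting from ``q0`` with small damped steps
    resolves the redundancy by minimal joint motion from ``q0``; the
    iteration is deterministic.
    """
    q = np.asarray(q0, dtype=float).copy()
    lam2 = damping * damping
    for _ in range(max_iter):
        pose = forward_kinematics(q, params)
        e_p = target.translation - pose.translation
        e_r = (target @ pose.inverse()).rotvec()
        e = np.concatenate([e_p, e_r])
        if np.linalg.norm(e) < tol:
            return q
        J = jacobian(q, params)
        dq = J.T @ np.linalg.solve(J @ J.T + lam2 * np.eye(6), e)
        step = np.linalg.norm(dq)
        if step > 0.5:                      # trust region: keep FK linearization valid
            dq *= 0.5 / step
        q = q + dq
    raise UnreachablePoseError("inverse kinematics did not converge: target may be out of reach")


def render_robot_log(traj: pd.DataFrame, field_params: TorqueFieldParams, scene: Scene,
                     orthosis: OrthosisParams, noise_sigma: float = 0.0,
                     seed: int | None = None):
    """Robot-level log: axis angles via IK along the trajectory and
    external joint torques ``tau_e = J^T f_env``, with optional per-joint
    Gaussian torque noise (N·m).  Columns: ``t, q1..q7, tau_e1..tau_e7``.
    """
    flange_log, truth = render_flange_log(traj, field_params, scene, orthosis,
                                          noise_sigma=0.0)
    n = len(traj)
    axes = np.empty((n, 7))
    tau = np.empty((n, 7))
    q_guess = scene.reference_axes
    for i in range(n):
        q = numeric_ik(truth.flange_poses[i], q_guess, scene.robot)
        axes[i] = q
        tau[i] = jacobian(q, scene.robot).T @ truth.wrench_env[i]
        q_guess = q
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        tau = tau + rng.normal(0.0, noise_sigma, size=tau.shape)
    truth.axes = axes
    truth.tau_e = tau
    cols = {"t": truth.t}
    for j in range(7):
        cols[f"q{j + 1}"] = axes[:, j]
    for j in range(7):
        cols[f"tau_e{j + 1}"] = tau[:, j]
    return pd.DataFrame(cols), truth


def drifted_elbow_points(traj: pd.DataFrame, scene: Scene, drift: float = 0.03,
                         onset: float = 0.7) -> np.ndarray:
    """Elbow trajectory with an end-stage translation of the rotation
    center, emulating the center drift seen near the range limit: beyond
    the ``onset`` fraction of the run the center translates smoothly by up
    to ``drift`` metres along +X."""
    _, elbows = _limb_motion(traj, scene)
    n = len(traj)
    s = np.linspace(0.0, 1.0, n)
    ramp = np.clip((s - onset) / (1.0 - onset), 0.0, 1.0) ** 2
    elbows = elbows.copy()
    elbows[:, 0] += drift * ramp
    return elbows
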