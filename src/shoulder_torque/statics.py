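"""Quasi-static extraction of the shoulder passive torque.

During slow robot-guided passive abduction the upper limb is in force and
moment balance at every instant: the shoulder reaction, the robot assist
wrench transmitted through the orthosis, and limb gravity cancel.  Under
that balance the passive torque — joint soft-tissue resistance plus the
gravity torque of the limb, taken as a whole — equals the moment, about
the shoulder rotation center, of the wrench the limb applies to the robot
flange.  The pipeline therefore: smooths the external joint torques,
recovers the flange wrench, removes the pre-measured orthosis gravity
contribution, and takes the moment about the fitted center.

Sign convention used throughout: a :class:`~.robot_model.Wrench` produced
by wrench recovery is the action of the environment ON the robot flange.
The assist wrench the robot applies to the limb is its reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shoulder_kinematics import ShoulderPosture
from .robot_model import Wrench
from .transforms import RigidTransform

__all__ = [
    "GRAVITY",
    "OrthosisParams",
    "LimbParams",
    "PassiveTorqueSample",
    "moving_average",
    "compensate_orthosis",
    "passive_torque",
    "repeatability_check",
    "RepeatabilityResult",
    "ComparisonError",
]

#: Standard gravitational acceleration (m/s^2).
GRAVITY = 9.80665


class ComparisonError(ValueError):
    """Two runs cannot be compared (e.g. non-overlapping posture ranges)."""


@dataclass(frozen=True)
class OrthosisParams:
    """Pre-measured orthosis gravity model: mass (kg) and center of mass in
    flange coordinates (m)."""

    mass: float
    com_in_flange: np.ndarray

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("orthosis mass must be nonnegative")
        object.__setattr__(self, "com_in_flange", np.asarray(self.com_in_flange, float).reshape(3))


@dataclass(frozen=True)
class LimbParams:
    """Rigid upper-limb surrogate used by the synthetic generator: total
    mass (kg) and distance of the mass center from the shoulder center
    along the arm axis (m)."""

    mass: float
    com_offset: float

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("limb mass must be nonnegative")
        if self.com_offset <= 0:
            raise ValueError("com_offset must be positive")


@dataclass(frozen=True)
class PassiveTorqueSample:
    """One (posture, passive torque) pair; torque in N·m, world axes."""

    posture: ShoulderPosture
    torque: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.torque, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("torque components must be finite")
        object.__setattr__(self, "torque", t)


def moving_average(series, window: int) -> np.ndarray:
    """Centered moving mean with symmetric edge shrinking.

    The half-width shrinks near the ends so the window stays centered and
    the output length equals the input length; a constant series is left
    unchanged everywhere including the edges.

    Parameters
    ----------
    series : (n,) or (n, d) array
    window : odd positive int, in samples
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    half = np.minimum((window - 1) // 2, np.minimum(np.arange(n), n - 1 - np.arange(n)))
    cs = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo = np.arange(n) - half
    hi = np.arange(n) + half + 1
    out = (cs[hi] - cs[lo]) / (2 * half + 1)[:, None]
    return out[:, 0] if squeeze else out


def orthosis_gravity_wrench(flange_pose: RigidTransform, orthosis: OrthosisParams) -> Wrench:
    """Wrench the orthosis weight exerts on the flange, at the flange
    origin in world axes: force (0, 0, -m g) and its moment
    ``(R · com_in_flange) x (0, 0, -m g)``."""
    fg = np.array([0.0, 0.0, -orthosis.mass * GRAVITY])
    r = flange_pose.rotate(orthosis.com_in_flange)
    return Wrench(force=fg, moment=np.cross(r, fg), frame="world")


def compensate_orthosis(wrench: Wrench, flange_pose: RigidTransform,
                        orthosis: OrthosisParams) -> Wrench:
    """Remove the orthosis gravity contribution from a measured flange
    wrench, leaving the wrench the limb alone applies to the robot."""
    g = orthosis_gravity_wrench(flange_pose, orthosis)
    return Wrench(wrench.force - g.force, wrench.moment - g.moment,
                  wrench.frame, wrench.singular)


def passive_torque(wrench: Wrench, flange_pose: RigidTransform, center) -> np.ndarray:
    """Shoulder passive torque M_P (N·m, world axes) from the
    orthosis-compensated flange wrench.

    ``wrench`` is the limb's action on the flange.  The robot's assist
    wrench on the limb is its reaction (F_R, M_R) = (-force, -moment); the
    moment of the assist force about the shoulder center is
    ``M_FR = (p_flange - center) x F_R`` and the quasi-static moment
    balance gives ``M_P = -M_R - M_FR``, which reduces to the moment of
    the limb-applied wrench about the center:

    ``M_P = moment + (p_flange - center) x force``.
    """
    c = np.asarray(center, dtype=float).reshape(3)
    arm = flange_pose.translation - c
    return wrench.moment + np.cross(arm, wrench.force)


@dataclass(frozen=True)
class RepeatabilityResult:
    passed: bool
    rms_fraction: float
    tol: float


def repeatability_check(run1, run2, tol: float = 0.1, n_grid: int = 100) -> RepeatabilityResult:
    """Compare two repeats of the same passive trajectory.

    Both runs are resampled onto a common elevation grid spanning the
    overlap of their elevation ranges; the metric is the rms difference of
    the three torque components over the grid, normalized by the combined
    torque range.  The run pair passes iff the metric is <= ``tol``.  The
    metric is symmetric in its arguments.

    Parameters
    ----------
    run1, run2 : pandas.DataFrame
        Columns ``elevation`` (rad) and ``mx, my, mz`` (N·m).
    """
    series = []
    for run in (run1, run2):
        e = np.asarray(run["elevation"], dtype=float)
        m = np.asarray(run[["mx", "my", "mz"]], dtype=float)
        order = np.argsort(e, kind="stable")
        series.append((e[order], m[order]))
    lo = max(series[0][0].min(), series[1][0].min())
    hi = min(series[0][0].max(), series[1][0].max())
    if not hi > lo:
        raise ComparisonError("runs have non-overlapping elevation ranges")
    grid = np.linspace(lo, hi, n_grid)
    interp = [
        np.column_stack([np.interp(grid, e, m[:, k]) for k in range(3)])
        for e, m in series
    ]
    diff = interp[0] - interp[1]
    all_torques = np.concatenate([series[0][1].ravel(), series[1][1].ravel()])
    span = float(all_torques.max() - all_torques.min())
    rms = float(np.sqrt(np.mean(diff**2)))
    frac = 0.0 if rms == 0.0 else (np.inf if span == 0.0 else rms / span)
    return RepeatabilityResult(passed=bool(frac <= tol), rms_fraction=frac, tol=tol)


def flange_speeds(times, positions) -> np.ndarray:
    """Finite-difference flange speed (m/s) for the quasi-static gate."""
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    if len(t) < 2:
        return np.zeros(len(t))
    v = np.gradient(p, t, axis=0)
    return np.linalg.norm(v, axis=1)
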