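"""Kinematics of a 7-DoF serial manipulator and flange wrench recovery.

The manipulator is modelled as seven revolute joints chained by fixed link
transforms.  Three operations are exposed:

* :func:`forward_kinematics` — flange pose in the robot world frame,
* :func:`jacobian` — 6x7 geometric Jacobian in world axes
  (rows 1-3 linear, rows 4-6 angular velocity),
* :func:`external_wrench` — least-squares recovery of the wrench the
  environment applies at the flange from the measured external joint
  torques, ``f = (J^T)^+ tau_e`` (principle of virtual work).

The world frame is right-handed with Z vertical up.  Angles are radians
throughout; degrees exist only at the CLI boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .transforms import RigidTransform, rotation_about

__all__ = [
    "RobotParams",
    "Wrench",
    "SingularConfigurationWarning",
    "default_robot",
    "load_robot_params",
    "forward_kinematics",
    "jacobian",
    "external_wrench",
]

N_JOINTS = 7

#: Relative singular-value cutoff for the Moore-Penrose pseudo-inverse.
PINV_RCOND = 1e-10


class SingularConfigurationWarning(UserWarning):
    """Jacobian rank below 6: the recovered wrench is the minimum-norm one."""


@dataclass(frozen=True)
class RobotParams:
    """Geometry of a 7-joint revolute serial arm.

    ``link_translations[i]`` is the fixed translation (m, parent frame)
    preceding joint ``i``; ``joint_axes[i]`` the unit rotation axis of
    joint ``i`` in its local frame; ``flange_offset`` the fixed translation
    from the last joint frame to the flange origin.
    """

    link_translations: np.ndarray
    joint_axes: np.ndarray
    flange_offset: np.ndarray
    name: str = "robot"
    joint_count: int = N_JOINTS

    def __post_init__(self) -> None:
        lt = np.asarray(self.link_translations, dtype=float).reshape(N_JOINTS, 3)
        ax = np.asarray(self.joint_axes, dtype=float).reshape(N_JOINTS, 3)
        fo = np.asarray(self.flange_offset, dtype=float).reshape(3)
        if self.joint_count != N_JOINTS:
            raise ValueError(f"joint_count must be {N_JOINTS}")
        norms = np.linalg.norm(ax, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("every joint axis must have unit norm")
        object.__setattr__(self, "link_translations", lt)
        object.__setattr__(self, "joint_axes", ax)
        object.__setattr__(self, "flange_offset", fo)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "link_translations": self.link_translations.tolist(),
            "joint_axes": self.joint_axes.tolist(),
            "flange_offset": self.flange_offset.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RobotParams":
        return cls(
            link_translations=np.asarray(d["link_translations"], dtype=float),
            joint_axes=np.asarray(d["joint_axes"], dtype=float),
            flange_offset=np.asarray(d["flange_offset"], dtype=float),
            name=d.get("name", "robot"),
        )


@dataclass(frozen=True)
class Wrench:
    """Force (N) + moment (N·m) at the flange origin, expressed in ``frame``."""

    force: np.ndarray
    moment: np.ndarray
    frame: str = "world"
    singular: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float).reshape(3)
        m = np.asarray(self.moment, dtype=float).reshape(3)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(m))):
            raise ValueError("wrench components must be finite")
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "moment", m)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.force, self.moment])

    def negated(self) -> "Wrench":
        return Wrench(-self.force, -self.moment, self.frame, self.singular)


def default_robot() -> RobotParams:
    """Default 7-DoF model: alternating z/y revolute axes, vertical link
    offsets 0.36 / 0.42 / 0.40 m and a 0.126 m flange plate, in the style of
    published lightweight collaborative-arm geometries.  All code paths take
    the geometry from :class:`RobotParams`; nothing downstream assumes these
    numbers.
    """
    z = (0.0, 0.0, 1.0)
    y = (0.0, 1.0, 0.0)
    return RobotParams(
        link_translations=[
            (0.0, 0.0, 0.36),
            (0.0, 0.0, 0.0),
            (0.0, 0.0, 0.42),
            (0.0, 0.0, 0.0),
            (0.0, 0.0, 0.40),
            (0.0, 0.0, 0.0),
            (0.0, 0.0, 0.0),
        ],
        joint_axes=[z, y, z, y, z, y, z],
        flange_offset=(0.0, 0.0, 0.126),
        name="default-7dof",
    )


def load_robot_params(path) -> RobotParams:
    """Read :class:`RobotParams` from a YAML config file (section ``robot``
    if present, else the document root)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "robot" in doc:
        doc = doc["robot"]
    return RobotParams.from_dict(doc)


def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (N_JOINTS,):
        raise ValueError(f"expected {N_JOINTS} joint angles, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("joint angles must be finite")
    return q


def _chain(q: np.ndarray, params: RobotParams):
    """Walk the chain; return (flange pose, per-joint world origins, axes)."""
    R = np.eye(3)
    p = np.zeros(3)
    origins = np.empty((N_JOINTS, 3))
    axes = np.empty((N_JOINTS, 3))
    for i in range(N_JOINTS):
        p = p + R @ params.link_translations[i]
        origins[i] = p
        axes[i] = R @ params.joint_axes[i]
        R = R @ rotation_about(params.joint_axes[i], q[i])
    p = p + R @ params.flange_offset
    return RigidTransform(R, p), origins, axes


def forward_kinematics(q, params: RobotParams) -> RigidTransform:
    """Flange pose ``T_F`` in the robot world frame for joint angles ``q`` (rad)."""
    q = _check_q(q)
    pose, _, _ = _chain(q, params)
    return pose


def jacobian(q, params: RobotParams) -> np.ndarray:
    """Geometric Jacobian (6x7) at ``q``: rows 0-2 linear, rows 3-5 angular
    velocity of the flange per unit joint rate, world axes."""
    q = _check_q(q)
    pose, origins, axes = _chain(q, params)
    J = np.empty((6, N_JOINTS))
    for i in range(N_JOINTS):
        J[:3, i] = np.cross(axes[i], pose.translation - origins[i])
        J[3:, i] = axes[i]
    return J


def external_wrench(q, tau_e, params: RobotParams) -> Wrench:
    """Recover the external wrench at the flange from external joint torques.

    Solves ``J(q)^T f = tau_e`` in the least-squares sense,
    ``f = (J^T)^+ tau_e`` with a Moore-Penrose pseudo-inverse (SVD,
    singular values below ``PINV_RCOND * sigma_max`` truncated).  ``f`` is
    the wrench the environment applies to the flange, at the flange origin,
    in world axes; it is exact whenever ``tau_e`` lies in the column space
    of ``J^T``.

    At a singular configuration (rank < 6) a
    :class:`SingularConfigurationWarning` is emitted and the result is
    flagged ``singular=True``.
    """
    q = _check_q(q)
    tau = np.asarray(tau_e, dtype=float).reshape(N_JOINTS)
    if not np.all(np.isfinite(tau)):
        raise ValueError("external joint torques must be finite")
    Jt = jacobian(q, params).T  # 7x6
    s = np.linalg.svd(Jt, compute_uv=False)
    singular = bool(np.sum(s > PINV_RCOND * s[0]) < 6)
    if singular:
        warnings.warn(
            "Jacobian rank < 6: wrench recovery is the minimum-norm least-squares "
            "solution at a singular configuration",
            SingularConfigurationWarning,
            stacklevel=2,
        )
    f = np.linalg.pinv(Jt, rcond=PINV_RCOND) @ tau
    return Wrench(force=f[:3], moment=f[3:], frame="world", singular=singular)
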