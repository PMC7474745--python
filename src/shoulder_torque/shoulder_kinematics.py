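"""Shoulder posture from robot kinematics.

The shoulder is idealised as a ball-and-socket joint about a fixed rotation
center.  The center is recovered by algebraic least-squares sphere fitting
of the elbow-landmark trajectory; a one-off calibration at a reference pose
(upper arm hanging vertically, all shoulder angles zero) fixes the constant
flange-to-shoulder transform; posture is then expressed with two
globographic angles — plane of elevation and elevation — which describe the
humerus direction on the sphere and deliberately exclude axial rotation of
the upper arm.

Angle conventions (declared, since the field offers several):

* elevation = angle between the center-to-elbow direction and the downward
  vertical (-Z), in [0, pi];
* plane of elevation = azimuth of that direction about the vertical,
  measured from the world X axis (the coronal axis, given the seated
  subject's body axes are aligned to the robot world frame), in (-pi, pi].

At the poles (elevation 0 or pi) the azimuth is undefined; it is reported
as 0 with an explicit degeneracy flag rather than as a silently arbitrary
value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .robot_model import RobotParams, forward_kinematics
from .transforms import RigidTransform

__all__ = [
    "DegenerateGeometryError",
    "SphereFit",
    "CalibrationRecord",
    "ShoulderPosture",
    "fit_sphere",
    "project_to_sphere",
    "calibrate",
    "shoulder_transform",
    "globographic_angles",
]

_UP = np.array([0.0, 0.0, 1.0])


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine the requested geometry."""


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center (m, world frame), radius (m), rms
    point-to-surface residual (m) and the number of points used."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "radius": float(self.radius),
            "rms_residual": float(self.rms_residual),
            "n_points": int(self.n_points),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SphereFit":
        return cls(np.asarray(d["center"], float), d["radius"], d["rms_residual"], d["n_points"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SphereFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CalibrationRecord:
    """Constant flange-to-shoulder transform plus the data that produced it:
    the reference axes pose and the manually measured elbow landmark in
    flange coordinates."""

    flange_to_shoulder: RigidTransform
    reference_axes: np.ndarray
    elbow_in_flange: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_axes", np.asarray(self.reference_axes, float).reshape(7))
        object.__setattr__(self, "elbow_in_flange", np.asarray(self.elbow_in_flange, float).reshape(3))

    def to_dict(self) -> dict:
        return {
            "flange_to_shoulder": self.flange_to_shoulder.to_flat(),
            "reference_axes": self.reference_axes.tolist(),
            "elbow_in_flange": self.elbow_in_flange.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationRecord":
        return cls(
            RigidTransform.from_flat(d["flange_to_shoulder"]),
            np.asarray(d["reference_axes"], float),
            np.asarray(d["elbow_in_flange"], float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CalibrationRecord":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ShoulderPosture:
    """Globographic description of one shoulder sample.

    ``degenerate`` is set when the elbow lies on the vertical through the
    center, where the plane of elevation is undefined (reported as 0).
    """

    plane_of_elevation: float
    elevation: float
    elbow_on_sphere: np.ndarray
    timestamp: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "elbow_on_sphere", np.asarray(self.elbow_on_sphere, float).reshape(3))
        if not 0.0 <= self.elevation <= np.pi + 1e-12:
            raise ValueError("elevation must lie in [0, pi]")

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.plane_of_elevation, self.elevation])


def fit_sphere(points) -> SphereFit:
    """Algebraic least-squares sphere through ``points`` ((n, 3), n >= 4).

    Linearises the sphere equation ``|p - c|^2 = r^2`` into
    ``2 p·c + (r^2 - |c|^2) = |p|^2``, a linear system in the center and a
    radius carrier, and solves it in one least-squares pass (Coope-style).
    Deterministic and closed-form; the rms point-to-surface residual is
    reported for diagnostics such as the former-part fitting rule.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 4 points, or a coplanar/degenerate configuration that
        leaves the sphere underdetermined.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    n = P.shape[0]
    if n < 4:
        raise DegenerateGeometryError("sphere fitting needs at least 4 points")
    A = np.hstack([2.0 * P, np.ones((n, 1))])
    b = np.einsum("ij,ij->i", P, P)
    x, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-12 * sv[0]:
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate")
    center = x[:3]
    r2 = x[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate configuration: nonpositive squared radius")
    radius = float(np.sqrt(r2))
    residual = np.linalg.norm(P - center, axis=1) - radius
    return SphereFit(center=center, radius=radius,
                     rms_residual=float(np.sqrt(np.mean(residual**2))), n_points=n)


def project_to_sphere(point, fit: SphereFit) -> np.ndarray:
    """Radial projection of ``point`` onto the fitted sphere: the
    intersection of the center-to-point ray with the surface."""
    p = np.asarray(point, dtype=float).reshape(3)
    d = p - fit.center
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise DegenerateGeometryError("projection undefined: point coincides with the sphere center")
    return fit.center + fit.radius * d / norm


def calibrate(reference_axes, radius: float, elbow_in_flange, params: RobotParams) -> CalibrationRecord:
    """Fix the constant flange-to-shoulder transform from the reference pose.

    At the reference pose every shoulder angle is zero: the upper arm hangs
    vertically, so the shoulder center sits directly above the elbow
    landmark at the fitted ``radius``, and the shoulder frame axes coincide
    with the world axes.  The returned transform therefore maps the flange
    frame to a world-aligned frame at the center, making
    :func:`shoulder_transform` the identity rotation at the reference pose
    by construction.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    reference_axes = np.asarray(reference_axes, dtype=float).reshape(7)
    elbow_in_flange = np.asarray(elbow_in_flange, dtype=float).reshape(3)
    T_F = forward_kinematics(reference_axes, params)
    center_world = T_F.apply(elbow_in_flange) + radius * _UP
    # shoulder frame at reference: rotation = world identity, origin = center
    flange_to_shoulder = T_F.inverse() @ RigidTransform(np.eye(3), center_world)
    return CalibrationRecord(flange_to_shoulder, reference_axes, elbow_in_flange)


def shoulder_transform(q, calib: CalibrationRecord, params: RobotParams) -> RigidTransform:
    """Shoulder frame pose ``T_s = T_F · (flange-to-shoulder)`` at joint
    angles ``q``: forward kinematics chained with the calibrated constant
    transform."""
    return forward_kinematics(q, params) @ calib.flange_to_shoulder


def globographic_angles(elbow_world, fit: SphereFit, timestamp: float = 0.0,
                        pole_tol: float = 1e-9) -> ShoulderPosture:
    """Two-angle globographic posture of the humerus from the elbow landmark.

    The elbow is projected radially onto the fitted sphere; elevation is
    the angle of the center-to-elbow direction from the downward vertical,
    and the plane of elevation is its azimuth about +Z from world X.  Axial
    rotation of the upper arm is excluded by construction (a direction on a
    sphere has no roll).
    """
    p = np.asarray(elbow_world, dtype=float).reshape(3)
    on_sphere = project_to_sphere(p, fit)
    u = (on_sphere - fit.center) / fit.radius
    elevation = float(np.arccos(np.clip(-u[2], -1.0, 1.0)))
    horizontal = np.hypot(u[0], u[1])
    if horizontal < pole_tol:
        return ShoulderPosture(0.0, elevation, on_sphere, timestamp, degenerate=True)
    plane = float(np.arctan2(u[1], u[0]))
    return ShoulderPosture(plane, elevation, on_sphere, timestamp, degenerate=False)
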