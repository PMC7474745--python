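"""Rigid-body transforms: the currency of all frame arithmetic in the package.

A :class:`RigidTransform` is a proper rigid motion (rotation + translation)
of 3-space, stored as a 3x3 orthonormal matrix with determinant +1 and a
3-vector in metres.  Composition follows the usual homogeneous-matrix
convention: ``(A @ B).apply(p) == A.apply(B.apply(p))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "rotation_about"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion of 3-space.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1.
    translation : (3,) ndarray
        Translation in metres.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("rigid transform components must be finite")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle rotation vector (rad) and a translation."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def translation_only(cls, translation) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(translation, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self`` followed-by-application-after ``other`` (matrix product)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        """Map a point (3,) or an array of points (n, 3) through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors) -> np.ndarray:
        """Apply the rotation part only (for free vectors such as forces)."""
        v = np.asarray(vectors, dtype=float)
        return v @ self.rotation.T

    def rotvec(self) -> np.ndarray:
        """Axis-angle vector (rad) of the rotation part."""
        return Rotation.from_matrix(self.rotation).as_rotvec()

    # -- serialization: 16 row-major numbers of the homogeneous matrix -------

    def to_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def to_flat(self) -> list[float]:
        return [float(x) for x in self.to_matrix().ravel()]

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        H = np.asarray(values, dtype=float).reshape(4, 4)
        return cls(H[:3, :3], H[:3, 3])

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


def rotation_about(axis, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    return Rotation.from_rotvec(axis / n * angle).as_matrix()
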