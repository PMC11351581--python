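"""Quaternion and rigid-transform helpers.

Conventions used throughout the package:

* right-handed world frame, X forward along the course, Y left, Z up;
* quaternions are stored ``(w, x, y, z)`` (scalar first), matching the
  session-log schema; scipy's ``Rotation`` (scalar last) is used internally;
* the device forward axis at identity orientation is +X, its up axis +Z and
  its left axis +Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


def as_rotation(q_wxyz) -> Rotation:
    """scipy Rotation from a scalar-first quaternion."""
    q = np.asarray(q_wxyz, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def to_wxyz(rot: Rotation) -> np.ndarray:
    """Scalar-first quaternion from a scipy Rotation."""
    return np.roll(rot.as_quat(), 1, axis=-1)


def quat_multiply(q1_wxyz, q2_wxyz) -> np.ndarray:
    """Hamilton product; rotation q1 applied after q2."""
    return to_wxyz(as_rotation(q1_wxyz) * as_rotation(q2_wxyz))


def check_unit_quaternion(q_wxyz, tol: float = 1e-6) -> np.ndarray:
    q = np.asarray(q_wxyz, dtype=float)
    if q.shape[-1] != 4:
        raise ConfigError(f"quaternion must have 4 components, got shape {q.shape}")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > tol):
        raise ConfigError(f"quaternion not normalized (|q| = {n})")
    return q


def yaw_quaternion(angle: float) -> np.ndarray:
    """Quaternion for a rotation of ``angle`` radians about world +Z."""
    return np.array([np.cos(angle / 2.0), 0.0, 0.0, np.sin(angle / 2.0)])


@dataclass
class Pose:
    """A rigid pose: position in meters plus scalar-first quaternion."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: IDENTITY_QUAT.copy())

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = check_unit_quaternion(
            np.asarray(self.orientation, dtype=float).reshape(4)
        )

    def rotation(self) -> Rotation:
        return as_rotation(self.orientation)

    def to_dict(self) -> dict:
        return {
            "position": self.position.tolist(),
            "orientation": self.orientation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(np.asarray(d["position"], float), np.asarray(d["orientation"], float))
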