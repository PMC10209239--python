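"""Rigid-transform algebra, Euler-angle conventions and rotation metrics.

Frame convention
----------------
``T_a_b`` (written :math:`T_a^b`) maps coordinates expressed in frame *b*
into frame *a*:  ``p_a = R @ p_b + t``.  Under this convention composing
``T_a_b`` with ``T_b_c`` yields ``T_a_c``, and both sides of the
camera/tracker coregistration identity used elsewhere in this package
evaluate to the same camera-to-marker transform.

Euler convention
----------------
Intrinsic Tait-Bryan yaw(Z) - pitch(Y) - roll(X), in degrees.  The camera
frame is x to the right, y down, z along the optical axis (depth from the
camera to the tracked object).  Every module imports the convention from
here; it is defined in exactly one place (`EULER_SEQ`).

Gimbal lock (|pitch| -> 90 deg) is resolved by the documented tie-break
roll := 0, signalled with a `GimbalLockWarning`, never with a silent NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

#: Intrinsic Tait-Bryan sequence: yaw about Z, then pitch about Y, then roll about X.
EULER_SEQ = "ZYX"

#: Orthonormality / unit-determinant tolerance for valid rotations.
ROTATION_TOL = 1e-9

#: |pitch| beyond which the Euler decomposition is flagged as gimbal-locked.
GIMBAL_LOCK_DEG = 89.9


class GimbalLockWarning(UserWarning):
    """Raised (as a warning) when an Euler decomposition hits gimbal lock."""


class InvalidTransformError(ValueError):
    """The supplied matrix is not a proper rigid transform."""


def _check_rotation(R: np.ndarray, tol: float = ROTATION_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise InvalidTransformError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise InvalidTransformError("rotation determinant is not +1")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: 3x3 rotation plus translation in mm.

    Immutable; all algebra returns new instances.  Construction validates
    the rotation to `ROTATION_TOL` unless ``_skip_check`` is set by
    internal callers that have already validated.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __init__(self, rotation, translation, *, _skip_check: bool = False):
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        if not _skip_check:
            R = _check_rotation(R)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), _skip_check=True)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise InvalidTransformError("bottom row must be [0 0 0 1]")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec_rad, translation) -> "RigidTransform":
        R = Rotation.from_rotvec(np.asarray(rotvec_rad, dtype=float)).as_matrix()
        return cls(R, translation, _skip_check=True)

    # -- conversions --------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotvec(self) -> np.ndarray:
        """Rotation-vector (axis * angle, radians) of the rotation part."""
        return Rotation.from_matrix(self.rotation).as_rotvec()

    # -- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map Nx3 (or length-3) point(s) from the source frame into the target frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition a . b: first apply b, then a (T_a_b @ T_b_c -> T_a_c)."""
    R = a.rotation @ b.rotation
    # re-orthonormalise drift from long chains so closure holds to ROTATION_TOL
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:  # cannot happen for proper inputs; guard anyway
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return RigidTransform(R, a.rotation @ b.translation + a.translation,
                          _skip_check=True)


def invert(t: RigidTransform) -> RigidTransform:
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation, _skip_check=True)


@dataclass
class EulerPose:
    """6-DoF pose: translation in mm, intrinsic ZYX yaw/pitch/roll in degrees."""

    x: float
    y: float
    z: float
    yaw: float
    pitch: float
    roll: float
    timestamp: Optional[float] = None
    valid: bool = True
    gimbal_locked: bool = field(default=False, compare=False)

    def translation(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def angles(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll])

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.yaw, self.pitch, self.roll])


def from_euler(p: EulerPose) -> RigidTransform:
    R = Rotation.from_euler(EULER_SEQ, [p.yaw, p.pitch, p.roll],
                            degrees=True).as_matrix()
    return RigidTransform(R, [p.x, p.y, p.z], _skip_check=True)


def to_euler(t: RigidTransform, timestamp: Optional[float] = None) -> EulerPose:
    """Decompose into yaw/pitch/roll (deg).  Near gimbal lock the tie-break
    roll := 0 is applied and the pose is flagged, with a `GimbalLockWarning`."""
    rot = Rotation.from_matrix(t.rotation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on its own at the singularity
        yaw, pitch, roll = rot.as_euler(EULER_SEQ, degrees=True)
    locked = abs(pitch) >= GIMBAL_LOCK_DEG
    if locked:
        # scipy already pushes the free angle into yaw; zero the roll
        roll = 0.0
        warnings.warn(
            f"pitch={pitch:.3f} deg is within {90 - GIMBAL_LOCK_DEG:.2g} deg of "
            "gimbal lock; roll set to 0 by convention",
            GimbalLockWarning,
            stacklevel=2,
        )
    x, y, z = t.translation
    return EulerPose(x, y, z, float(yaw), float(pitch), float(roll),
                     timestamp=timestamp, gimbal_locked=bool(locked))


def rotation_distance(a: RigidTransform, b: RigidTransform) -> float:
    """Geodesic angle (degrees, in [0, 180]) between the two rotations."""
    rel = a.rotation.T @ b.rotation
    return float(np.degrees(Rotation.from_matrix(rel).magnitude()))


def translation_distance(a: RigidTransform, b: RigidTransform) -> float:
    """Euclidean distance (mm) between the two translations."""
    return float(np.linalg.norm(a.translation - b.translation))


def random_transform(rng: np.random.Generator,
                     max_angle_deg: float = 180.0,
                     max_translation_mm: float = 1000.0) -> RigidTransform:
    """Seeded random proper rigid transform (uniform axis, uniform angle)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_rotvec(axis * angle, t)
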