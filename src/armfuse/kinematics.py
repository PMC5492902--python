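"""Rotation and rigid-transform algebra shared by the estimators and the simulator.

Conventions
-----------
* Quaternions are **scalar-first** ``(w, x, y, z)`` and use the Hamilton
  product.  ``q`` and ``-q`` encode the same rotation; utilities that
  compare attitudes account for the double cover.
* ``quat_to_rotmat(q)`` returns the direction-cosine matrix ``R`` such that
  ``v_world = R @ v_body``; the body angular velocity ``omega`` then obeys
  ``dR/dt = R @ skew(omega)`` and ``dq/dt = 1/2 * q ⊗ (0, omega)``.
* Rigid transforms are rotation-then-translation pairs acting as
  ``x -> R @ x + t`` and compose left-to-right along a kinematic chain.
* The Denavit-Hartenberg rows follow the classic (distal) convention:
  ``Rz(theta + theta_offset) · Tz(d) · Tx(a) · Rx(alpha)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "UNIT_TOL",
    "Quaternion",
    "RigidTransform",
    "DhRow",
    "skew",
    "vex",
    "quat_mul",
    "quat_conjugate",
    "quat_normalize",
    "quat_rate",
    "integrate_quat",
    "quat_to_rotmat",
    "rotmat_to_quat",
    "quat_angle",
    "rotation_about_axis",
    "random_rotation",
    "geodesic_angle",
    "chain_compose",
    "dh_transform",
]

#: orthonormality / unit-norm tolerance used throughout the package
UNIT_TOL = 1e-9

#: identity quaternion (w, x, y, z)
QUAT_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

Quaternion = np.ndarray  # shape (4,), scalar-first, unit norm


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} has non-finite components")
    return v


def skew(omega) -> np.ndarray:
    """Skew-symmetric (cross-product) matrix: ``skew(w) @ v == cross(w, v)``."""
    wx, wy, wz = _as_vec3(omega, "omega")
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def vex(S) -> np.ndarray:
    """Inverse of :func:`skew` for an (approximately) antisymmetric matrix."""
    S = np.asarray(S, dtype=float)
    A = 0.5 * (S - S.T)
    return np.array([A[2, 1], A[0, 2], A[1, 0]])


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------

def quat_mul(p, q) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` of scalar-first quaternions."""
    pw, px, py, pz = np.asarray(p, dtype=float)
    qw, qx, qy, qz = np.asarray(q, dtype=float)
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot normalize a zero or non-finite quaternion")
    return q / n


def omega_matrix(omega) -> np.ndarray:
    """4x4 matrix ``Q(w)`` with ``dq/dt = Q(w) @ q`` for body rate ``w``.

    ``Q(w) = 1/2 [[0, -w^T], [w, -skew(w)]]`` — the matrix form of the
    right-multiplication ``1/2 q ⊗ (0, w)``.
    """
    w = _as_vec3(omega, "omega")
    Q = np.zeros((4, 4))
    Q[0, 1:] = -w
    Q[1:, 0] = w
    Q[1:, 1:] = -skew(w)
    return 0.5 * Q


def quat_rate(q, omega) -> np.ndarray:
    """Quaternion derivative for body angular velocity: ``1/2 q ⊗ (0, w)``."""
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("q must be a 4-vector quaternion")
    return omega_matrix(omega) @ q


def integrate_quat(q, omega, T: float, exact: bool = False) -> np.ndarray:
    """Advance attitude ``q`` by body rate ``omega`` held for ``T`` seconds.

    Default is the first-order update ``q + T * quat_rate(q, w)`` followed by
    renormalization, matching the discrete ``(Phi*T + I)`` filters; with
    ``exact=True`` the axis-angle exponential is used instead.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    w = _as_vec3(omega, "omega")
    q = np.asarray(q, dtype=float)
    if exact:
        angle = np.linalg.norm(w) * T
        if angle < 1e-300:
            return quat_normalize(q)
        axis = w / np.linalg.norm(w)
        half = 0.5 * angle
        dq = np.concatenate([[np.cos(half)], np.sin(half) * axis])
        return quat_normalize(quat_mul(q, dq))
    return quat_normalize(q + T * quat_rate(q, w))


def quat_to_rotmat(q) -> np.ndarray:
    """Unit quaternion -> direction cosine matrix (body-to-world)."""
    q = quat_normalize(q)
    # scipy uses scalar-last ordering
    return _ScipyRotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def rotmat_to_quat(R, tol: float = 1e-6) -> np.ndarray:
    """Rotation matrix -> unit quaternion in the ``w >= 0`` hemisphere."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be 3x3")
    if np.linalg.norm(R.T @ R - np.eye(3)) > tol or np.linalg.det(R) < 0:
        raise ValueError("R is not a proper rotation matrix")
    x, y, z, w = _ScipyRotation.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return quat_normalize(q)


def rotmats_to_quats(R) -> np.ndarray:
    """Batched rotation matrices (N,3,3) -> scalar-first quaternions (N,4)
    in the ``w >= 0`` hemisphere."""
    R = np.asarray(R, dtype=float)
    q = _ScipyRotation.from_matrix(R).as_quat()  # (N,4) scalar-last
    q = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    q[q[:, 0] < 0] *= -1
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def quats_to_rotmats(q) -> np.ndarray:
    """Batched scalar-first quaternions (N,4) -> rotation matrices (N,3,3)."""
    q = np.asarray(q, dtype=float)
    return _ScipyRotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


def quat_angle(p, q) -> float:
    """Geodesic angle (rad) between two attitudes, sign-ambiguity aware."""
    d = abs(float(np.dot(quat_normalize(p), quat_normalize(q))))
    return 2.0 * np.arccos(min(d, 1.0))


def geodesic_angle(R1, R2) -> float:
    """Rotation angle (rad) of ``R1ᵀ R2``."""
    c = 0.5 * (np.trace(np.asarray(R1).T @ np.asarray(R2)) - 1.0)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit ``axis`` by ``angle`` radians."""
    a = _as_vec3(axis, "axis")
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("axis must be non-zero")
    a = a / n
    S = skew(a)
    return np.eye(3) + np.sin(angle) * S + (1.0 - np.cos(angle)) * (S @ S)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion sampled on S³)."""
    q = rng.standard_normal(4)
    return quat_to_rotmat(quat_normalize(q))


# ---------------------------------------------------------------------------
# rigid transforms and kinematic-chain composition
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation in SO(3), metres)."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.R.shape != (3, 3) or self.t.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and 3-vector")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, A) -> "RigidTransform":
        A = np.asarray(A, dtype=float)
        return cls(A[:3, :3], A[:3, 3])

    def as_matrix(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.R
        A[:3, 3] = self.t
        return A

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other`` (apply ``other`` first in the child frame)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def apply(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.R @ x.T).T + self.t


def chain_compose(transforms) -> RigidTransform:
    """Left-to-right composition of homogeneous transforms along a chain."""
    transforms = list(transforms)
    if not transforms:
        raise ValueError("chain_compose requires at least one transform")
    out = transforms[0]
    for T in transforms[1:]:
        out = out.compose(T)
    return out


@dataclass(frozen=True)
class DhRow:
    """Classic Denavit-Hartenberg row: link length a (m), twist alpha (rad),
    offset d (m), joint-angle offset theta_offset (rad)."""

    a: float = 0.0
    alpha: float = 0.0
    d: float = 0.0
    theta_offset: float = 0.0


def dh_transform(row: DhRow, theta: float) -> RigidTransform:
    """``Rz(theta + offset) · Tz(d) · Tx(a) · Rx(alpha)``."""
    th = theta + row.theta_offset
    ct, st = np.cos(th), np.sin(th)
    ca, sa = np.cos(row.alpha), np.sin(row.alpha)
    R = np.array(
        [
            [ct, -st * ca, st * sa],
            [st, ct * ca, -ct * sa],
            [0.0, sa, ca],
        ]
    )
    t = np.array([row.a * ct, row.a * st, row.d])
    return RigidTransform(R, t)
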