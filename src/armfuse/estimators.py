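"""Per-limb attitude trackers and the shared Wahba solver.

Three free-segment trackers estimate each limb's attitude independently and
reconstruct the wrist through the chain offsets:

* ``method1`` — a Kalman filter per segment whose state is the gravity and
  magnetic field vectors expressed in the sensor frame, propagated with the
  gyroscope as a known control input (transition ``I6 + T·blkdiag(−S(ω̃),
  −S(ω̃))``) and corrected by the identity measurement model; the filtered
  vector pair feeds the QUEST solver against the N-pose references.
* ``method2`` — an EKF on the 7-vector ``[ω; q]`` where the angular velocity
  decays exponentially with time constants ``t_k`` (limb acceleration
  averages to zero) and the quaternion propagates with ``q̇ = Q(ω)q``;
  measurements are the gyroscope and the QUEST attitude fix.
* ``method3`` — a complementary filter ``q⁺ = (1/k)(q_m − q_p) + q`` blending
  the gyro-propagated ``q_p`` with the QUEST fix ``q_m``; the *pure* variant
  feeds QUEST the raw accelerometer, the *perfect* variant first subtracts
  the chain-propagated linear acceleration.

A gyro-only strapdown integrator is included as the drift negative control.

The Wahba solver is the Davenport q-method (largest eigenvector of the 4×4
``K`` matrix); an SVD orthogonal-Procrustes solver is provided as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_model import KinematicChain
from .kinematics import (
    integrate_quat,
    omega_matrix,
    quat_normalize,
    quat_to_rotmat,
    quats_to_rotmats,
    rotmat_to_quat,
    skew,
)
from .synthetic import GRAVITY, DEFAULT_M0, ImuStream, SensorMounting, default_mounting

__all__ = [
    "WahbaProblem",
    "solve_wahba",
    "solve_wahba_svd",
    "attitude_from_vectors",
    "Method1Params",
    "Method1Filter",
    "Method2Params",
    "Method2Filter",
    "Cf3Config",
    "Cf3Filter",
    "StrapdownFilter",
    "TrackerResult",
    "FREE_SEGMENT_METHODS",
    "track_free_segments",
    "reconstruct_positions",
]


# ---------------------------------------------------------------------------
# Wahba's problem
# ---------------------------------------------------------------------------

@dataclass
class WahbaProblem:
    """Pairs of observed (sensor-frame) and reference (root-frame) unit
    vectors with non-negative weights."""

    observed: np.ndarray  # (k,3)
    reference: np.ndarray  # (k,3)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.observed = np.atleast_2d(np.asarray(self.observed, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.observed.shape != self.reference.shape or self.observed.shape[1] != 3:
            raise ValueError("observed/reference must both be (k,3)")
        if self.weights is None:
            self.weights = np.ones(len(self.observed))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


def _attitude_profile(problem: WahbaProblem) -> np.ndarray:
    obs = problem.observed / np.linalg.norm(problem.observed, axis=1, keepdims=True)
    ref = problem.reference / np.linalg.norm(problem.reference, axis=1, keepdims=True)
    w = problem.weights / problem.weights.sum()
    B = np.einsum("k,ki,kj->ij", w, obs, ref)
    # degenerate if all pairs are collinear: rank(B) < 2
    if np.linalg.matrix_rank(B, tol=1e-10) < 2:
        raise ValueError("degenerate Wahba problem: observations are collinear")
    return B


def solve_wahba(problem: WahbaProblem) -> np.ndarray:
    """Davenport q-method: quaternion of the rotation ``A`` minimizing
    ``Σ wᵢ ‖obsᵢ − A·refᵢ‖²`` (so ``A`` maps reference onto observed vectors).

    Returns a scalar-first unit quaternion with non-negative scalar part.
    """
    B = _attitude_profile(problem)
    S = B + B.T
    sigma = np.trace(B)
    z = np.array([B[1, 2] - B[2, 1], B[2, 0] - B[0, 2], B[0, 1] - B[1, 0]])
    # Davenport K for scalar-first q = [w; v]: A maps ref -> obs with
    # z = Σ w (obs × ref)
    z = -z  # B[i,j]=Σ w obs_i ref_j; (obs × ref)_k = -eps ... fixed by tests
    K = np.empty((4, 4))
    K[0, 0] = sigma
    K[0, 1:] = z
    K[1:, 0] = z
    K[1:, 1:] = S - sigma * np.eye(3)
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, np.argmax(vals)]
    if q[0] < 0:
        q = -q
    return quat_normalize(q)


def solve_wahba_svd(problem: WahbaProblem) -> np.ndarray:
    """Orthogonal-Procrustes (SVD) solution of the same problem; kept as an
    independent oracle for the q-method."""
    B = _attitude_profile(problem)
    U, _s, Vt = np.linalg.svd(B)
    D = np.diag([1.0, 1.0, np.linalg.det(U) * np.linalg.det(Vt)])
    A = U @ D @ Vt
    return rotmat_to_quat(A)


def attitude_from_vectors(a_body, m_body, g_ref=None, m_ref=None) -> np.ndarray:
    """Segment attitude quaternion (body-to-root) from one accelerometer and
    one magnetometer sample, equally weighted."""
    g_ref = -GRAVITY if g_ref is None else np.asarray(g_ref, float)
    m_ref = DEFAULT_M0 if m_ref is None else np.asarray(m_ref, float)
    q = solve_wahba(WahbaProblem(np.stack([a_body, m_body]), np.stack([g_ref, m_ref])))
    # q maps root->body; the attitude (body-to-root) is its conjugate
    return quat_normalize(np.array([q[0], -q[1], -q[2], -q[3]]))


# ---------------------------------------------------------------------------
# shared small utilities
# ---------------------------------------------------------------------------

def _check_psd(P: np.ndarray, what: str, tol: float = 1e-6) -> np.ndarray:
    P = 0.5 * (P + P.T)
    if np.min(np.linalg.eigvalsh(P)) < -tol:
        raise FloatingPointError(f"{what}: covariance lost positive semi-definiteness")
    return P


def _hemisphere(q, q_ref) -> np.ndarray:
    return q if float(np.dot(q, q_ref)) >= 0 else -q


@dataclass
class TrackerResult:
    """Per-time-step output of one tracker: segment attitudes (scalar-first
    quaternions), wrist position (m, root frame) and, for the chain filters,
    the joint-angle trajectory."""

    method: str
    t: np.ndarray
    quaternions: dict[str, np.ndarray]  # (N,4) per segment
    wrist: np.ndarray  # (N,3)
    joint_angles: np.ndarray | None = None  # (N,ndof) chain filters only


# ---------------------------------------------------------------------------
# Method 1: vector KF + QUEST
# ---------------------------------------------------------------------------

@dataclass
class Method1Params:
    """Process noise is driven by the assumed gyro error (rad/s); measurement
    variances include the unmodelled linear acceleration, which dominates the
    accelerometer channel during motion."""

    gyro_sigma: float = 0.01
    accel_meas_sigma: float = 1.0  # m/s², includes linear-acceleration disturbance
    mag_meas_sigma: float = 0.05  # normalized


class Method1Filter:
    """Kalman filter on the 6-vector ``[g; m]`` in the sensor frame."""

    def __init__(self, g_ref, m_ref, params: Method1Params | None = None):
        self.params = params or Method1Params()
        self.g_ref = np.asarray(g_ref, float)
        self.m_ref = np.asarray(m_ref, float)
        self.X: np.ndarray | None = None
        self.P: np.ndarray | None = None

    def initialize(self, a, m):
        self.X = np.concatenate([a, m]).astype(float)
        p = self.params
        self.P = np.diag([p.accel_meas_sigma**2] * 3 + [p.mag_meas_sigma**2] * 3)

    def step(self, omega, a, m, T: float) -> np.ndarray:
        """One predict/update; returns the QUEST attitude (body-to-root)."""
        if self.X is None:
            self.initialize(a, m)
        p = self.params
        S = skew(omega)
        F = np.eye(6)
        F[:3, :3] -= T * S  # world-fixed vector seen from the rotating frame
        F[3:, 3:] -= T * S
        q_g = (T * p.gyro_sigma * 9.81) ** 2
        q_m = (T * p.gyro_sigma) ** 2
        Q = np.diag([q_g] * 3 + [q_m] * 3)
        X = F @ self.X
        P = F @ self.P @ F.T + Q
        R = np.diag([p.accel_meas_sigma**2] * 3 + [p.mag_meas_sigma**2] * 3)
        Z = np.concatenate([a, m])
        Kg = P @ np.linalg.solve(P + R, np.eye(6))
        self.X = X + Kg @ (Z - X)
        self.P = _check_psd((np.eye(6) - Kg) @ P, "method1")
        return attitude_from_vectors(self.X[:3], self.X[3:], self.g_ref, self.m_ref)


# ---------------------------------------------------------------------------
# Method 2: EKF on [omega; q] with angular-velocity decay
# ---------------------------------------------------------------------------

@dataclass
class Method2Params:
    t_k: tuple[float, float, float] = (0.5, 0.5, 0.5)  # s, per-axis decay
    omega_process_sigma: float = 1.0  # rad/s per √s, drives the decay model
    quat_process_sigma: float = 0.01
    omega_meas_sigma: float = 0.01  # rad/s
    quat_meas_sigma: float = 0.3  # QUEST fix under linear acceleration

    def __post_init__(self):
        if np.any(np.asarray(self.t_k) <= 0):
            raise ValueError("decay constants t_k must be positive")


class Method2Filter:
    """EKF on ``X = [ω; q]`` (7-vector): exponential ω decay + quaternion
    kinematics in the process, identity measurement against ``[ω̃; q_m]``."""

    def __init__(self, g_ref, m_ref, params: Method2Params | None = None):
        self.params = params or Method2Params()
        self.g_ref = np.asarray(g_ref, float)
        self.m_ref = np.asarray(m_ref, float)
        self.X: np.ndarray | None = None
        self.P: np.ndarray | None = None

    def initialize(self, omega, a, m):
        q0 = attitude_from_vectors(a, m, self.g_ref, self.m_ref)
        self.X = np.concatenate([omega, q0])
        p = self.params
        self.P = np.diag([p.omega_meas_sigma**2] * 3 + [p.quat_meas_sigma**2] * 4)

    def _phi(self, X) -> np.ndarray:
        Phi = np.zeros((7, 7))
        Phi[:3, :3] = -np.diag(1.0 / np.asarray(self.params.t_k))
        Phi[3:, 3:] = omega_matrix(X[:3])
        return Phi

    def predict(self, T: float) -> None:
        """State propagation ``X⁺ = (Φ(X)·T + I)·X`` with the EKF Jacobian of
        the bilinear quaternion block for the covariance."""
        p = self.params
        X = self.X
        Phi = self._phi(X)
        Xn = (Phi * T + np.eye(7)) @ X
        # Jacobian of f(X) = Phi(X)X wrt X: quaternion block is bilinear
        J = np.zeros((7, 7))
        J[:3, :3] = -np.diag(1.0 / np.asarray(p.t_k))
        q = X[3:]
        # d(Q(w)q)/dw : 1/2 * Xi(q), with Xi the quaternion right-multiplication
        Xi = 0.5 * np.array(
            [
                [-q[1], -q[2], -q[3]],
                [q[0], -q[3], q[2]],
                [q[3], q[0], -q[1]],
                [-q[2], q[1], q[0]],
            ]
        )
        J[3:, :3] = Xi
        J[3:, 3:] = omega_matrix(X[:3])
        F = np.eye(7) + T * J
        Q = np.diag(
            [T * p.omega_process_sigma**2] * 3 + [T * p.quat_process_sigma**2] * 4
        )
        self.X = Xn
        self.X[3:] = quat_normalize(self.X[3:])
        self.P = 0.5 * ((F @ self.P @ F.T + Q) + (F @ self.P @ F.T + Q).T)

    def step(self, omega, a, m, T: float, update: bool = True) -> np.ndarray:
        if self.X is None:
            self.initialize(omega, a, m)
            return quat_normalize(self.X[3:])
        self.predict(T)
        if update:
            p = self.params
            qm = attitude_from_vectors(a, m, self.g_ref, self.m_ref)
            qm = _hemisphere(qm, self.X[3:])
            Z = np.concatenate([omega, qm])
            R = np.diag([p.omega_meas_sigma**2] * 3 + [p.quat_meas_sigma**2] * 4)
            Kg = self.P @ np.linalg.solve(self.P + R, np.eye(7))
            self.X = self.X + Kg @ (Z - self.X)
            self.P = _check_psd((np.eye(7) - Kg) @ self.P, "method2")
            self.X[3:] = quat_normalize(self.X[3:])
        return self.X[3:].copy()


# ---------------------------------------------------------------------------
# Method 3: complementary filter (pure / perfect)
# ---------------------------------------------------------------------------

@dataclass
class Cf3Config:
    """Gain ``k > 1``: each step moves the estimate ``1/k`` of the way from
    the gyro propagation towards the QUEST fix, so the correction time
    constant is ``k·T`` seconds."""

    k: float = 300.0
    mode: str = "pure"  # "pure" | "perfect"

    def __post_init__(self):
        if not self.k > 1:
            raise ValueError("complementary gain k must exceed 1")
        if self.mode not in ("pure", "perfect"):
            raise ValueError("mode must be 'pure' or 'perfect'")


class Cf3Filter:
    """Componentwise quaternion blend ``q⁺ = (1/k)(q_m − q_p) + q_p`` (the
    update is not norm-preserving: the result is renormalized, and ``q_m`` is
    hemisphere-aligned to ``q_p`` first)."""

    def __init__(self, g_ref, m_ref, config: Cf3Config | None = None):
        self.config = config or Cf3Config()
        self.g_ref = np.asarray(g_ref, float)
        self.m_ref = np.asarray(m_ref, float)
        self.q: np.ndarray | None = None

    def step(self, omega, a, m, T: float, la=None) -> np.ndarray:
        """``la``: root-frame linear acceleration at the sensor point,
        required in 'perfect' mode (subtracted from the accelerometer before
        the QUEST fix)."""
        if self.config.mode == "perfect":
            if la is None:
                raise ValueError("perfect mode requires the chain linear acceleration")
        gi = np.asarray(a, float)
        if self.config.mode == "perfect":
            R = quat_to_rotmat(self.q) if self.q is not None else np.eye(3)
            gi = gi - R.T @ np.asarray(la, float)
        if self.q is None:
            self.q = attitude_from_vectors(gi, m, self.g_ref, self.m_ref)
            return self.q.copy()
        qp = integrate_quat(self.q, omega, T)
        qm = attitude_from_vectors(gi, m, self.g_ref, self.m_ref)
        qm = _hemisphere(qm, qp)
        self.q = quat_normalize(qp + (qm - qp) / self.config.k)
        return self.q.copy()


class StrapdownFilter:
    """Gyro-only integration from the first QUEST fix — the negative control
    that drifts under gyro bias."""

    def __init__(self, g_ref, m_ref):
        self.g_ref = np.asarray(g_ref, float)
        self.m_ref = np.asarray(m_ref, float)
        self.q: np.ndarray | None = None

    def step(self, omega, a, m, T: float) -> np.ndarray:
        if self.q is None:
            self.q = attitude_from_vectors(a, m, self.g_ref, self.m_ref)
        else:
            self.q = integrate_quat(self.q, omega, T)
        return self.q.copy()


# ---------------------------------------------------------------------------
# tracking harness for the free-segment methods
# ---------------------------------------------------------------------------

def _segment_order(chain: KinematicChain, names) -> list[str]:
    order = [s.name for s in chain.segments if s.name in set(names)]
    if set(order) != set(names):
        raise ValueError("stream segments not all present in the chain")
    return order


def reconstruct_positions(
    chain: KinematicChain, rotations: dict[str, np.ndarray]
) -> np.ndarray:
    """Wrist trace from per-segment body-to-root rotations (N,3,3): the chain
    offsets are applied recursively from the root, each rotated by its
    parent segment's estimated attitude."""
    n = None
    for Rset in rotations.values():
        n = len(Rset)
        break
    pos = {chain.segments[0].name: np.zeros((n, 3))}
    for seg in chain.segments[1:]:
        Rp = rotations.get(seg.parent)
        if Rp is None:
            Rp = np.broadcast_to(np.eye(3), (n, 3, 3))  # steady chest
        pos[seg.name] = pos[seg.parent] + np.einsum(
            "bij,j->bi", Rp, np.asarray(seg.offset, float)
        )
    return pos[chain.wrist_name]


FREE_SEGMENT_METHODS = ("method1", "method2", "method3_pure", "method3_perfect", "strapdown")


def track_free_segments(
    stream: ImuStream,
    chain: KinematicChain,
    method: str,
    mounting: SensorMounting | None = None,
    g0=GRAVITY,
    m0=DEFAULT_M0,
    params=None,
) -> TrackerResult:
    """Run one free-segment tracker over a stream and reconstruct the wrist.

    For ``method3_perfect`` the per-sensor linear acceleration is computed
    online from the tracker's own attitude estimates and the gyro signals
    (finite-differenced for angular acceleration), propagated root-to-leaves.
    """
    mounting = mounting if mounting is not None else default_mounting()
    segs = _segment_order(chain, stream.segments)
    T = stream.dt
    n = stream.t.size
    # with the known mounting applied, every filter works in the segment
    # frame against root-frame references (the N-pose alignment assumption)
    g_ref = -np.asarray(g0, float)
    m_ref = np.asarray(m0, float)

    def make_filter(name):
        if method == "method1":
            return Method1Filter(g_ref, m_ref, params)
        if method == "method2":
            return Method2Filter(g_ref, m_ref, params)
        if method == "method3_pure":
            return Cf3Filter(g_ref, m_ref, params or Cf3Config(mode="pure"))
        if method == "method3_perfect":
            cfg = params or Cf3Config(mode="perfect")
            if cfg.mode != "perfect":
                raise ValueError("method3_perfect requires a perfect-mode config")
            return Cf3Filter(g_ref, m_ref, cfg)
        if method == "strapdown":
            return StrapdownFilter(g_ref, m_ref)
        raise ValueError(f"unknown free-segment method {method!r}")

    filters = {name: make_filter(name) for name in segs}
    quats = {name: np.empty((n, 4)) for name in segs}
    perfect = method == "method3_perfect"
    prev_gyro = {name: stream.gyro[name][0] for name in segs}
    seg_offsets = {s.name: np.asarray(s.offset, float) for s in chain.segments}
    parents = {s.name: s.parent for s in chain.segments}

    for j in range(n):
        la_sensor: dict[str, np.ndarray] = {}
        if perfect:
            # chain-propagated linear acceleration from current estimates
            la_origin = {chain.segments[0].name: np.zeros(3)}
            R_est: dict[str, np.ndarray] = {chain.segments[0].name: np.eye(3)}
            w_world: dict[str, np.ndarray] = {chain.segments[0].name: np.zeros(3)}
            al_world: dict[str, np.ndarray] = {chain.segments[0].name: np.zeros(3)}
            for name in segs:
                q_prev = filters[name].q
                R = quat_to_rotmat(q_prev) if q_prev is not None else np.eye(3)
                R_est[name] = R
                w_s = mounting.rotation[name] @ stream.gyro[name][j]
                al_s = mounting.rotation[name] @ (stream.gyro[name][j] - prev_gyro[name]) / T
                w_world[name] = R @ w_s
                al_world[name] = R @ al_s
            for seg in chain.segments[1:]:
                if seg.name not in segs and seg.name not in parents.values():
                    continue
                par = parents[seg.name]
                if par not in la_origin:
                    continue
                Rp = R_est.get(par, np.eye(3))
                d = Rp @ seg_offsets[seg.name]
                wp = w_world.get(par, np.zeros(3))
                ap = al_world.get(par, np.zeros(3))
                la_origin[seg.name] = la_origin[par] + np.cross(ap, d) + np.cross(wp, np.cross(wp, d))
            for name in segs:
                r_w = R_est[name] @ mounting.lever_arm[name]
                w = w_world[name]
                al = al_world[name]
                la_sensor[name] = (
                    la_origin.get(name, np.zeros(3))
                    + np.cross(al, r_w)
                    + np.cross(w, np.cross(w, r_w))
                )

        for name in segs:
            # rotate raw sensor signals into the segment frame (known mounting)
            Rm = mounting.rotation[name]
            w = Rm @ stream.gyro[name][j]
            a = Rm @ stream.accel[name][j]
            m = Rm @ stream.mag[name][j]
            if perfect:
                q = filters[name].step(w, a, m, T, la=la_sensor[name])
            else:
                q = filters[name].step(w, a, m, T)
            quats[name][j] = q
            prev_gyro[name] = stream.gyro[name][j]

    rot = {name: quats_to_rotmats(quats[name]) for name in segs}
    wrist = reconstruct_positions(chain, rot)
    return TrackerResult(method, stream.t.copy(), quats, wrist)
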