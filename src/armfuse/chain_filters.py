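"""Chain-constrained trackers: an EKF and a UKF over the articulated arm.

Both filters share the state ``X = [q₁ q̇₁ q̈₁ … qₙ q̈ₙ]`` (joint angles,
rates and accelerations) and the constant-angular-acceleration process
model; they differ in the measurement handling:

* ``method4`` — EKF.  Measurements per arm sensor are the accelerometer and
  gyroscope predicted through the chain, the magnetometer reduced to its
  heading (yaw) component only, plus the normalized wrist bearing from the
  chest camera at its slower rate.  The observation matrix is obtained by
  central finite differences of the measurement function.
* ``method5`` — UKF.  The full nine-axis prediction (three-axis
  magnetometer, lever-arm accelerometer model) is pushed through the
  unscented transformation; no linearization, no camera.

The measurement prediction is evaluated in batch over EKF perturbation
states / UKF sigma points with a single chain-kinematics pass per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .arm_model import _UnitChain, _cross, build_dh_from_chain, KinematicChain
from .estimators import TrackerResult, _check_psd
from .kinematics import rotmats_to_quats
from .synthetic import (
    CameraModel,
    GRAVITY,
    DEFAULT_M0,
    ImuStream,
    SensorMounting,
    default_mounting,
)

__all__ = [
    "ChainFilterState",
    "UtConfig",
    "ChainFilterParams",
    "process_matrix",
    "process_predict",
    "method4_measurement",
    "method5_measurement",
    "Method4Filter",
    "Method5Filter",
    "method4_track",
    "method5_track",
]

log = logging.getLogger(__name__)


@dataclass
class ChainFilterState:
    """Stacked per-joint blocks ``[q, q̇, q̈]``; covariance 3n×3n."""

    X: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n = self.X.size
        if n % 3 or self.P.shape != (n, n):
            raise ValueError("state must stack [q, qd, qdd] blocks with 3n×3n covariance")

    @property
    def ndof(self) -> int:
        return self.X.size // 3

    @property
    def q(self) -> np.ndarray:
        return self.X[0::3]

    @property
    def qd(self) -> np.ndarray:
        return self.X[1::3]

    @property
    def qdd(self) -> np.ndarray:
        return self.X[2::3]


@dataclass
class UtConfig:
    """Unscented-transformation scaling (Merwe): small spread ``alpha``,
    Gaussian-optimal ``beta = 2``, ``kappa = 0``."""

    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0

    def weights(self, n: int) -> tuple[float, np.ndarray, np.ndarray]:
        lam = self.alpha**2 * (n + self.kappa) - n
        wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
        wc = wm.copy()
        wm[0] = lam / (n + lam)
        wc[0] = wm[0] + 1.0 - self.alpha**2 + self.beta
        return lam, wm, wc


@dataclass
class ChainFilterParams:
    """Noise settings shared by both chain filters.

    ``jerk_sigma`` is the white-jerk PSD driving the constant-acceleration
    process model (rad/s³·√Hz); measurement σ defaults track the synthetic
    sensor noise with a margin for residual model error.
    """

    jerk_sigma: float = 200.0
    accel_sigma: float = 0.07  # m/s²
    gyro_sigma: float = 0.01  # rad/s
    heading_sigma: float = 0.05  # rad (method 4)
    mag_sigma: float = 0.02  # normalized (method 5)
    camera_sigma: float = 0.01  # normalized image coordinates
    init_angle_sigma: float = 0.1  # rad
    init_rate_sigma: float = 0.5
    init_acc_sigma: float = 5.0


# ---------------------------------------------------------------------------
# process model
# ---------------------------------------------------------------------------

def process_matrix(ndof: int, T: float) -> np.ndarray:
    """Block-diagonal constant-angular-acceleration transition."""
    if T <= 0:
        raise ValueError("T must be positive")
    blk = np.array([[1.0, T, T * T / 2.0], [0.0, 1.0, T], [0.0, 0.0, 1.0]])
    F = np.zeros((3 * ndof, 3 * ndof))
    for i in range(ndof):
        F[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = blk
    return F


def _process_noise(ndof: int, T: float, jerk_sigma: float) -> np.ndarray:
    qj = jerk_sigma**2
    blk = qj * np.array(
        [
            [T**5 / 20.0, T**4 / 8.0, T**3 / 6.0],
            [T**4 / 8.0, T**3 / 3.0, T**2 / 2.0],
            [T**3 / 6.0, T**2 / 2.0, T],
        ]
    )
    Q = np.zeros((3 * ndof, 3 * ndof))
    for i in range(ndof):
        Q[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = blk
    return Q


def process_predict(state: ChainFilterState, T: float, jerk_sigma: float = 0.0) -> ChainFilterState:
    """One constant-acceleration prediction with additive process noise."""
    F = process_matrix(state.ndof, T)
    Q = _process_noise(state.ndof, T, jerk_sigma) if jerk_sigma > 0 else 0.0
    return ChainFilterState(F @ state.X, F @ state.P @ F.T + Q)


# ---------------------------------------------------------------------------
# measurement prediction (batched over states)
# ---------------------------------------------------------------------------

def _chain_sensor_predictions(
    chain: _UnitChain,
    XB: np.ndarray,
    mounting: SensorMounting,
    g0: np.ndarray,
    m0: np.ndarray,
) -> tuple[dict, np.ndarray]:
    """Per-sensor predicted (ã, ω̃, m̃) for a batch of states (B, 3n), plus
    the batch wrist positions."""
    Q = XB[:, 0::3]
    Qd = XB[:, 1::3]
    Qdd = XB[:, 2::3]
    sig = chain.signals(Q, Qd, Qdd)
    out = {}
    for name in mounting.segments:
        s = sig[name]
        Rm = mounting.rotation[name]
        r = mounting.lever_arm[name]
        w_w = np.einsum("bij,bj->bi", s.R, s.omega)
        a_w = np.einsum("bij,bj->bi", s.R, s.alpha)
        r_w = np.einsum("bij,j->bi", s.R, r)
        acc_sensor = s.acc + _cross(a_w, r_w) + _cross(w_w, _cross(w_w, r_w))
        to_sensor = np.einsum("ji,bjk->bik", Rm, np.transpose(s.R, (0, 2, 1)))
        out[name] = {
            "accel": np.einsum("bij,bj->bi", to_sensor, acc_sensor - g0),
            "gyro": np.einsum("ji,bj->bi", Rm, s.omega),
            "mag": np.einsum("bij,j->bi", to_sensor, m0),
            "R_seg": s.R,
        }
    return out, sig[chain.wrist_name].pos


def _heading_of_measured_field(R_seg: np.ndarray, Rm: np.ndarray, m_meas: np.ndarray) -> np.ndarray:
    """Yaw of the measured magnetometer vector rotated to the root frame with
    the state's segment attitude — the heading-only magnetometer reduction."""
    m_w = np.einsum("bij,j->bi", R_seg, Rm @ m_meas)
    return np.arctan2(m_w[:, 1], m_w[:, 0])


def method4_measurement(
    X,
    chain: _UnitChain,
    mounting: SensorMounting,
    m_meas: dict[str, np.ndarray] | None = None,
    camera: CameraModel | None = None,
    g0=GRAVITY,
    m0=DEFAULT_M0,
) -> np.ndarray:
    """Predicted measurement vector for state(s) ``X`` (…,3n): per sensor
    ``[ã(3), ω̃(3), heading(1)]`` plus the normalized wrist bearing when a
    camera model is given.  Heading rows need the measured magnetometer
    sample (the reduction rotates it into the root frame); without it the
    predicted field heading is used."""
    XB = np.atleast_2d(np.asarray(X, dtype=float))
    preds, wrist = _chain_sensor_predictions(chain, XB, mounting, np.asarray(g0, float), np.asarray(m0, float))
    cols = []
    ref_heading = np.arctan2(m0[1], m0[0])
    for name in mounting.segments:
        p = preds[name]
        cols += [p["accel"], p["gyro"]]
        if m_meas is not None and name in m_meas:
            h = _heading_of_measured_field(p["R_seg"], mounting.rotation[name], m_meas[name])
        else:
            m_w = np.einsum("bij,bj->bi", p["R_seg"], np.einsum("ij,bj->bi", mounting.rotation[name], p["mag"]))
            h = np.arctan2(m_w[:, 1], m_w[:, 0])
        cols.append((h - ref_heading)[:, None])
    if camera is not None:
        p_cam = camera.pose.inverse().apply(wrist)
        z = p_cam[:, 2]
        if np.any(z <= 0):
            raise ValueError("wrist behind the camera for a batch state")
        cols.append(p_cam[:, :2] / z[:, None])
    out = np.concatenate(cols, axis=1)
    return out[0] if np.asarray(X).ndim == 1 else out


def method5_measurement(
    X,
    chain: _UnitChain,
    mounting: SensorMounting,
    g0=GRAVITY,
    m0=DEFAULT_M0,
) -> np.ndarray:
    """Predicted nine-axis stack ``[ã(3), ω̃(3), m̃(3)]`` per sensor: the
    lever-arm accelerometer model and the full three-axis magnetometer."""
    XB = np.atleast_2d(np.asarray(X, dtype=float))
    preds, _ = _chain_sensor_predictions(chain, XB, mounting, np.asarray(g0, float), np.asarray(m0, float))
    cols = []
    for name in mounting.segments:
        p = preds[name]
        cols += [p["accel"], p["gyro"], p["mag"]]
    out = np.concatenate(cols, axis=1)
    return out[0] if np.asarray(X).ndim == 1 else out


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.remainder(a + np.pi, 2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# Method 4: EKF with finite-difference Jacobian
# ---------------------------------------------------------------------------

class Method4Filter:
    """EKF on the joint-space state with multi-rate camera aiding."""

    def __init__(
        self,
        chain: _UnitChain,
        mounting: SensorMounting,
        params: ChainFilterParams | None = None,
        camera: CameraModel | None = None,
        g0=GRAVITY,
        m0=DEFAULT_M0,
        fd_step: float = 1e-6,
        use_camera: bool = True,
    ):
        self.chain = chain
        self.mounting = mounting
        self.params = params or ChainFilterParams()
        self.camera = camera if use_camera else None
        self.g0 = np.asarray(g0, float)
        self.m0 = np.asarray(m0, float)
        self.fd_step = fd_step
        #: normalized innovation squared per step (whiteness diagnostics)
        self.nis_history: list[float] = []
        n = chain.ndof
        p = self.params
        P0 = np.diag(
            ([p.init_angle_sigma**2, p.init_rate_sigma**2, p.init_acc_sigma**2] * n)
        )
        self.state = ChainFilterState(np.zeros(3 * n), P0)

    def _stack_measurement(self, accel, gyro, mag, cam_row):
        z = []
        rvar = []
        p = self.params
        ref_heading = np.arctan2(self.m0[1], self.m0[0])
        for name in self.mounting.segments:
            z += [accel[name], gyro[name], [0.0]]  # heading innovation target is 0
            rvar += [p.accel_sigma**2] * 3 + [p.gyro_sigma**2] * 3 + [p.heading_sigma**2]
        has_cam = (
            self.camera is not None
            and cam_row is not None
            and np.all(np.isfinite(cam_row))
        )
        if has_cam:
            z.append(cam_row)
            rvar += [p.camera_sigma**2] * 2
        return np.concatenate([np.atleast_1d(v) for v in z]), np.array(rvar), has_cam

    def step(self, accel, gyro, mag, T: float, cam_row=None) -> ChainFilterState:
        """One predict/update.  ``accel``/``gyro``/``mag``: dicts of per-sensor
        samples; ``cam_row``: (2,) normalized wrist bearing or None/NaN."""
        st = process_predict(self.state, T, self.params.jerk_sigma)
        z, rvar, has_cam = self._stack_measurement(accel, gyro, mag, cam_row)

        n = st.X.size
        h = self.fd_step
        XB = np.concatenate(
            [st.X[None, :], st.X[None, :] + h * np.eye(n), st.X[None, :] - h * np.eye(n)]
        )
        try:
            HB = method4_measurement(
                XB, self.chain, self.mounting,
                m_meas=mag, camera=self.camera if has_cam else None,
                g0=self.g0, m0=self.m0,
            )
        except ValueError:
            # wrist behind the camera at a perturbed state: drop the camera rows
            has_cam = False
            z, rvar, _ = self._stack_measurement(accel, gyro, mag, None)
            HB = method4_measurement(
                XB, self.chain, self.mounting, m_meas=mag, camera=None,
                g0=self.g0, m0=self.m0,
            )
        h0 = HB[0]
        H = (HB[1 : n + 1] - HB[n + 1 :]).T / (2 * h)

        # heading rows live on a circle: wrap the innovation
        m_sens = len(self.mounting.segments)
        head_rows = [7 * i + 6 for i in range(m_sens)]
        nu = z - h0
        nu[head_rows] = _wrap(nu[head_rows])

        R = np.diag(rvar)
        S = H @ st.P @ H.T + R
        try:
            K = np.linalg.solve(S, H @ st.P).T
        except np.linalg.LinAlgError:
            log.warning("method4: singular innovation covariance, regularizing")
            S = S + 1e-9 * np.eye(S.shape[0])
            K = np.linalg.solve(S, H @ st.P).T
        nis = float(nu @ np.linalg.solve(S, nu))
        self.nis_history.append(nis)
        if nis > 5 * len(nu):
            log.debug("method4: large normalized innovation %.1f (dim %d)", nis, len(nu))
        X = st.X + K @ nu
        IKH = np.eye(n) - K @ H
        P = IKH @ st.P @ IKH.T + K @ R @ K.T
        self.state = ChainFilterState(X, _check_psd(P, "method4"))
        return self.state


# ---------------------------------------------------------------------------
# Method 5: UKF
# ---------------------------------------------------------------------------

class Method5Filter:
    """UKF over the (Denavit-Hartenberg) chain with the nine-axis lever-arm
    measurement model pushed through the unscented transformation."""

    def __init__(
        self,
        chain: _UnitChain,
        mounting: SensorMounting,
        params: ChainFilterParams | None = None,
        ut: UtConfig | None = None,
        g0=GRAVITY,
        m0=DEFAULT_M0,
        measurement_fn=None,
    ):
        self.chain = chain
        self.mounting = mounting
        self.params = params or ChainFilterParams()
        self.ut = ut or UtConfig()
        self.g0 = np.asarray(g0, float)
        self.m0 = np.asarray(m0, float)
        # injectable for cross-checks (e.g. linear-Gaussian equivalence)
        self._measurement_fn = measurement_fn
        n = chain.ndof
        p = self.params
        P0 = np.diag([p.init_angle_sigma**2, p.init_rate_sigma**2, p.init_acc_sigma**2] * n)
        self.state = ChainFilterState(np.zeros(3 * n), P0)

    def _sigma_points(self, X, P, lam) -> np.ndarray:
        n = X.size
        A = None
        jitter = 0.0
        for attempt in range(6):
            try:
                A = np.linalg.cholesky((n + lam) * (P + jitter * np.eye(n)))
                break
            except np.linalg.LinAlgError:
                jitter = 1e-12 if jitter == 0.0 else jitter * 100.0
                log.warning("method5: covariance Cholesky failed, jitter=%g", jitter)
        if A is None:
            raise FloatingPointError("method5: covariance not factorizable")
        return np.concatenate([X[None, :], X[None, :] + A.T, X[None, :] - A.T])

    def step(self, accel, gyro, mag, T: float) -> ChainFilterState:
        p = self.params
        n = self.state.X.size
        lam, wm, wc = self.ut.weights(n)

        # sigma points through the (linear) process model
        sp = self._sigma_points(self.state.X, self.state.P, lam)
        F = process_matrix(self.chain.ndof, T)
        sp = sp @ F.T
        Xp = wm @ sp
        dX = sp - Xp
        Pp = np.einsum("k,ki,kj->ij", wc, dX, dX) + _process_noise(
            self.chain.ndof, T, p.jerk_sigma
        )
        Pp = 0.5 * (Pp + Pp.T)
        # redraw around the predicted density so the additive process noise
        # enters the measurement statistics
        sp = self._sigma_points(Xp, Pp, lam)
        dX = sp - Xp

        # unscented measurement update
        if self._measurement_fn is not None:
            ZS = np.atleast_2d(self._measurement_fn(sp))
            z = np.asarray(accel, float)  # caller passes the raw measurement vector
            R = np.asarray(gyro, float)  # and its covariance
        else:
            ZS = method5_measurement(sp, self.chain, self.mounting, self.g0, self.m0)
            rvar = []
            z = []
            for name in self.mounting.segments:
                z += [accel[name], gyro[name], mag[name]]
                rvar += [p.accel_sigma**2] * 3 + [p.gyro_sigma**2] * 3 + [p.mag_sigma**2] * 3
            z = np.concatenate(z)
            R = np.diag(rvar)
        zm = wm @ ZS
        dZ = ZS - zm
        Pzz = np.einsum("k,ki,kj->ij", wc, dZ, dZ) + R
        Pxz = np.einsum("k,ki,kj->ij", wc, dX, dZ)
        K = np.linalg.solve(Pzz.T, Pxz.T).T
        X = Xp + K @ (z - zm)
        P = Pp - K @ Pzz @ K.T
        self.state = ChainFilterState(X, _check_psd(P, "method5"))
        return self.state


# ---------------------------------------------------------------------------
# tracking harnesses
# ---------------------------------------------------------------------------

def _result_from_states(method, chain, stream, Qtraj) -> TrackerResult:
    sig = chain.signals(Qtraj)
    quats = {}
    for name in chain.segment_names:
        if name in (chain.wrist_name,):
            continue
        quats[name] = rotmats_to_quats(sig[name].R)
    return TrackerResult(
        method, stream.t.copy(), quats, sig[chain.wrist_name].pos, joint_angles=Qtraj
    )


def method4_track(
    stream: ImuStream,
    chain: _UnitChain,
    mounting: SensorMounting | None = None,
    params: ChainFilterParams | None = None,
    camera: CameraModel | None = None,
    use_camera: bool = True,
    g0=GRAVITY,
    m0=DEFAULT_M0,
) -> TrackerResult:
    """Run the chain EKF over a stream (camera rows consumed at their own
    rate; NaN rows — marker not visible — are skipped)."""
    mounting = mounting if mounting is not None else default_mounting()
    if camera is None and stream.camera is not None:
        camera = CameraModel()
    filt = Method4Filter(chain, mounting, params, camera, g0, m0, use_camera=use_camera)
    n = stream.t.size
    cam_lookup = {}
    if stream.camera is not None and use_camera:
        for tk, row in zip(stream.camera_t, stream.camera):
            cam_lookup[int(round(tk / stream.dt))] = row
    Qtraj = np.empty((n, chain.ndof))
    for j in range(n):
        st = filt.step(
            {k: v[j] for k, v in stream.accel.items()},
            {k: v[j] for k, v in stream.gyro.items()},
            {k: v[j] for k, v in stream.mag.items()},
            stream.dt,
            cam_row=cam_lookup.get(j),
        )
        Qtraj[j] = st.q
    return _result_from_states("method4", chain, stream, Qtraj)


def method5_track(
    stream: ImuStream,
    chain: _UnitChain,
    mounting: SensorMounting | None = None,
    params: ChainFilterParams | None = None,
    ut: UtConfig | None = None,
    g0=GRAVITY,
    m0=DEFAULT_M0,
) -> TrackerResult:
    """Run the chain UKF; ``chain`` may be the axis-parametrized chain (its
    Denavit-Hartenberg form is built automatically) or a ``DhChain``."""
    mounting = mounting if mounting is not None else default_mounting()
    if isinstance(chain, KinematicChain):
        chain = build_dh_from_chain(chain)
    filt = Method5Filter(chain, mounting, params, ut, g0, m0)
    n = stream.t.size
    Qtraj = np.empty((n, chain.ndof))
    for j in range(n):
        st = filt.step(
            {k: v[j] for k, v in stream.accel.items()},
            {k: v[j] for k, v in stream.gyro.items()},
            {k: v[j] for k, v in stream.mag.items()},
            stream.dt,
        )
        Qtraj[j] = st.q
    return _result_from_states("method5", chain, stream, Qtraj)
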