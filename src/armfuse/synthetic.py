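"""Synthetic stand-in for the motion-capture recordings: scripted
functional-movement trajectories, ground-truth poses, and noisy mIMU and
wrist-camera measurements obtained by forward-evaluating the sensor models.

A movement script drives exactly one functional joint with the C²
waveform ``q(t) = A sin⁴(π φ(t))``, where the phase ``φ`` advances by one
per cycle at the slow period for the first cycles and at the fast period
for the last ones.  ``sin⁴`` has vanishing value, velocity *and*
acceleration at every cycle boundary, so slow and fast cycles concatenate
into a twice continuously differentiable trajectory and cycle boundaries
fall at exact scripted instants.  A static lead-in (default 1 s) precedes
the first cycle; it doubles as the N-pose reference hold used by the
evaluation alignment.

Accelerometers measure specific force: with world gravity ``g0`` (default
``(0,0,-9.81)`` m/s²) a static sensor reads ``-g0`` rotated into its frame.
The magnetic reference ``m0`` is a unit vector with a dip-angle-like
inclination, homogeneous over the workspace unless a disturbance is
scripted.  The wrist camera is modelled directly in normalized image
coordinates, co-located with the chest; samples behind the camera or far
outside the field of view are emitted as NaN (marker not visible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arm_model import MOVEMENT_JOINT, _UnitChain, default_arm_chain
from .kinematics import RigidTransform, rotation_about_axis

__all__ = [
    "GRAVITY",
    "DEFAULT_M0",
    "MotionScript",
    "SensorMounting",
    "NoiseModel",
    "CameraModel",
    "ImuStream",
    "GroundTruth",
    "generate_trajectory",
    "synthesize_imu",
    "synthesize_camera",
    "project_normalized",
    "perturb_calibration",
    "default_mounting",
]

#: world gravity vector (m/s²), root frame z up
GRAVITY = np.array([0.0, 0.0, -9.81])

#: default normalized magnetic field: pointing anteriorly with a 60° downward dip
DEFAULT_M0 = np.array([np.cos(np.deg2rad(60.0)), 0.0, -np.sin(np.deg2rad(60.0))])

MOVEMENTS = ("EFE", "EPS", "SFE", "SAA", "SIR")

#: default movement amplitudes (rad): 90° at the elbow, 60° at the shoulder
DEFAULT_AMPLITUDE = {
    "EFE": np.pi / 2,
    "EPS": np.pi / 2,
    "SFE": np.pi / 3,
    "SAA": np.pi / 3,
    "SIR": np.pi / 3,
}


@dataclass
class MotionScript:
    """One functional movement: ``slow_cycles`` at ``slow_period`` followed by
    ``fast_cycles`` at ``fast_period``, after a static ``lead_in`` hold."""

    movement: str = "EFE"
    amplitude: float | None = None
    slow_cycles: int = 7
    fast_cycles: int = 2
    slow_period: float = 2.0
    fast_period: float = 1.0
    lead_in: float = 1.0

    def __post_init__(self):
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if self.amplitude is None:
            self.amplitude = DEFAULT_AMPLITUDE[self.movement]
        if abs(self.amplitude) > np.pi:
            raise ValueError("amplitude exceeding π is not a functional movement")
        if self.slow_period <= 0 or self.fast_period <= 0 or self.lead_in < 0:
            raise ValueError("periods must be positive and lead_in non-negative")

    @property
    def duration(self) -> float:
        return self.lead_in + self.slow_cycles * self.slow_period + self.fast_cycles * self.fast_period

    def cycle_starts(self) -> np.ndarray:
        """Start time of each cycle plus the final end time."""
        starts = [self.lead_in]
        for _ in range(self.slow_cycles):
            starts.append(starts[-1] + self.slow_period)
        for _ in range(self.fast_cycles):
            starts.append(starts[-1] + self.fast_period)
        return np.array(starts)

    def angle(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Scripted angle and its first two analytic derivatives at times ``t``."""
        t = np.asarray(t, dtype=float)
        starts = self.cycle_starts()
        q = np.zeros_like(t)
        qd = np.zeros_like(t)
        qdd = np.zeros_like(t)
        periods = [self.slow_period] * self.slow_cycles + [self.fast_period] * self.fast_cycles
        for k, P in enumerate(periods):
            m = (t >= starts[k]) & (t < starts[k + 1])
            phi = (t[m] - starts[k]) / P
            s = np.sin(np.pi * phi)
            c = np.cos(np.pi * phi)
            A = self.amplitude
            q[m] = A * s**4
            qd[m] = 4 * A * np.pi / P * s**3 * c
            qdd[m] = 4 * A * (np.pi / P) ** 2 * s**2 * (3 * c**2 - s**2)
        return q, qd, qdd


@dataclass
class SensorMounting:
    """Per-segment sensor pose: ``rotation`` maps sensor coordinates into the
    segment frame; ``lever_arm`` is the sensor origin in the segment frame (m)."""

    rotation: dict[str, np.ndarray]
    lever_arm: dict[str, np.ndarray]

    def __post_init__(self):
        for name, R in self.rotation.items():
            R = np.asarray(R, dtype=float)
            if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9:
                raise ValueError(f"mounting rotation for {name!r} is not orthonormal")
            self.rotation[name] = R
        self.lever_arm = {k: np.asarray(v, dtype=float) for k, v in self.lever_arm.items()}

    @property
    def segments(self) -> list[str]:
        return list(self.rotation)


def default_mounting(chain=None) -> SensorMounting:
    """Identity mounting rotations, sensors at mid-segment on the arm."""
    return SensorMounting(
        rotation={"upper_arm": np.eye(3), "forearm": np.eye(3)},
        lever_arm={"upper_arm": np.array([0.0, 0.0, -0.15]), "forearm": np.array([0.0, 0.0, -0.125])},
    )


@dataclass
class NoiseModel:
    """Sensor noise: white σ per channel, a constant gyro bias magnitude and an
    optional scripted magnetic disturbance (callable ``t -> (3,) offset``)."""

    gyro_sigma: float = 0.005  # rad/s
    gyro_bias: float = 0.01  # rad/s, constant per sensor, random direction
    accel_sigma: float = 0.05  # m/s²
    mag_sigma: float = 0.01  # normalized units
    camera_sigma: float = 0.005  # normalized image coordinates
    mag_disturbance: object = None  # callable t -> (3,) added to m0, or None
    seed: int = 0

    def __post_init__(self):
        if min(self.gyro_sigma, self.accel_sigma, self.mag_sigma, self.camera_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.gyro_bias < 0:
            raise ValueError("gyro bias magnitude must be non-negative")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, None, seed)


@dataclass
class CameraModel:
    """Normalized-coordinate wrist camera rigidly attached to the chest.

    ``pose`` maps camera coordinates to the root frame (default: at the chest
    origin, optical axis pitched 45° down from anterior).  ``rate_divisor``
    subsamples the IMU grid (8 -> 12.5 Hz at 100 Hz).  ``max_coord`` bounds
    the normalized coordinates considered visible.
    """

    pose: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            # columns: x_cam (subject's right), y_cam (down-ish), z_cam (optical axis)
            np.column_stack(
                [
                    [0.0, -1.0, 0.0],
                    [-np.sin(np.pi / 4), 0.0, -np.cos(np.pi / 4)],
                    [np.cos(np.pi / 4), 0.0, -np.sin(np.pi / 4)],
                ]
            ),
            np.zeros(3),
        )
    )
    rate_divisor: int = 8
    min_depth: float = 0.01
    max_coord: float = 3.0


@dataclass
class GroundTruth:
    """Simulator truth: joint state trajectory, segment poses, wrist positions
    and cycle boundaries, all consistent with the chain forward kinematics."""

    t: np.ndarray
    Q: np.ndarray
    Qd: np.ndarray
    Qdd: np.ndarray
    chain: _UnitChain
    script: MotionScript
    signals: object  # ChainSignals over the time axis
    wrist: np.ndarray  # (N,3)
    cycle_bounds: np.ndarray  # (n_cycles+1,) sample indices

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class ImuStream:
    """Time-aligned measurement streams at the IMU rate plus an optional
    camera channel on a subsampled grid (NaN rows = marker not visible)."""

    t: np.ndarray
    accel: dict[str, np.ndarray]  # m/s², sensor frame
    gyro: dict[str, np.ndarray]  # rad/s, sensor frame
    mag: dict[str, np.ndarray]  # normalized, sensor frame
    camera_t: np.ndarray | None = None
    camera: np.ndarray | None = None  # (Nc,2) normalized coordinates
    rate_hz: float = 100.0

    @property
    def segments(self) -> list[str]:
        return list(self.accel)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_trajectory(
    script: MotionScript, chain: _UnitChain | None = None, T: float = 0.01
) -> GroundTruth:
    """Render the scripted single-DoF movement into ground-truth kinematics."""
    chain = chain if chain is not None else default_arm_chain()
    joint = MOVEMENT_JOINT[script.movement]
    if joint not in chain.joint_names:
        raise ValueError(f"chain has no joint {joint!r} for movement {script.movement}")
    j = chain.joint_names.index(joint)

    n = int(round(script.duration / T))
    t = np.arange(n) * T
    q, qd, qdd = script.angle(t)
    Q = np.zeros((n, chain.ndof))
    Qd = np.zeros_like(Q)
    Qdd = np.zeros_like(Q)
    Q[:, j] = q
    Qd[:, j] = qd
    Qdd[:, j] = qdd

    sig = chain.signals(Q, Qd, Qdd)
    starts = script.cycle_starts()
    bounds = np.clip(np.round(starts / T).astype(int), 0, n)
    if script.amplitude == 0.0:
        bounds = bounds[:1]  # static: no cycles
    return GroundTruth(t, Q, Qd, Qdd, chain, script, sig, sig[chain.wrist_name].pos, bounds)


def synthesize_imu(
    truth: GroundTruth,
    mounting: SensorMounting | None = None,
    noise: NoiseModel | None = None,
    g0: np.ndarray = GRAVITY,
    m0: np.ndarray = DEFAULT_M0,
    camera: CameraModel | None = None,
) -> ImuStream:
    """Forward-evaluate the mIMU (and optional camera) measurement models.

    Per sensor ``s`` on segment ``i`` with mounting rotation ``R_si`` and
    lever arm ``r``:

    * ``ã = R_siᵀ R_iᵀ (acc_sensor − g0) + w_a`` — specific force, where
      ``acc_sensor`` adds the lever-arm terms ``α×r + ω×(ω×r)`` to the
      segment-origin linear acceleration,
    * ``ω̃ = R_siᵀ ω_i + b + w_ω`` — body rate plus constant bias,
    * ``m̃ = R_siᵀ R_iᵀ m0(t) + w_m``.
    """
    mounting = mounting if mounting is not None else default_mounting()
    noise = noise if noise is not None else NoiseModel()
    g0 = np.asarray(g0, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if not np.isclose(np.linalg.norm(g0), 9.81, atol=0.2):
        raise ValueError("|g0| must be ≈ 9.81 m/s²")
    if np.linalg.norm(np.cross(g0 / np.linalg.norm(g0), m0 / np.linalg.norm(m0))) < 1e-6:
        raise ValueError("m0 parallel to g0: attitude unobservable")

    rng = np.random.default_rng(noise.seed)
    sig = truth.signals
    n = truth.n_samples

    if noise.mag_disturbance is not None:
        m_field = m0[None, :] + np.asarray([noise.mag_disturbance(tk) for tk in truth.t])
    else:
        m_field = np.broadcast_to(m0, (n, 3))

    accel: dict[str, np.ndarray] = {}
    gyro: dict[str, np.ndarray] = {}
    mag: dict[str, np.ndarray] = {}
    for name in mounting.segments:
        s = sig[name]
        Rm = mounting.rotation[name]
        r = mounting.lever_arm[name]
        # sensor-point acceleration in the root frame
        w_w = np.einsum("bij,bj->bi", s.R, s.omega)
        a_w = np.einsum("bij,bj->bi", s.R, s.alpha)
        r_w = np.einsum("bij,j->bi", s.R, r)
        acc_sensor = s.acc + np.cross(a_w, r_w) + np.cross(w_w, np.cross(w_w, r_w))
        # express in the sensor frame: Rmᵀ · Rᵀ
        to_sensor = np.einsum("ji,bjk->bik", Rm, np.transpose(s.R, (0, 2, 1)))
        a_meas = np.einsum("bij,bj->bi", to_sensor, acc_sensor - g0)
        m_meas = np.einsum("bij,bj->bi", to_sensor, m_field)
        w_meas = np.einsum("ji,bj->bi", Rm, s.omega)

        bias = np.zeros(3)
        if noise.gyro_bias > 0:
            v = rng.standard_normal(3)
            bias = noise.gyro_bias * v / np.linalg.norm(v)
        a_meas = a_meas + noise.accel_sigma * rng.standard_normal((n, 3))
        w_meas = w_meas + bias + noise.gyro_sigma * rng.standard_normal((n, 3))
        m_meas = m_meas + noise.mag_sigma * rng.standard_normal((n, 3))
        accel[name], gyro[name], mag[name] = a_meas, w_meas, m_meas

    stream = ImuStream(truth.t.copy(), accel, gyro, mag, rate_hz=1.0 / (truth.t[1] - truth.t[0]))
    if camera is not None:
        stream.camera_t, stream.camera = synthesize_camera(truth, camera, noise, rng=rng)
    return stream


def project_normalized(point_cam) -> np.ndarray:
    """Perspective division: ``(x, y, z) -> (x/z, y/z)``; requires ``z > 0``."""
    p = np.asarray(point_cam, dtype=float)
    if p.ndim == 1:
        if p[2] <= 0:
            raise ValueError("cheirality violation: non-positive depth")
        return p[:2] / p[2]
    if np.any(p[:, 2] <= 0):
        raise ValueError("cheirality violation: non-positive depth")
    return p[:, :2] / p[:, 2:3]


def synthesize_camera(
    truth: GroundTruth,
    camera: CameraModel | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized wrist-bearing samples on the camera's subsampled time grid.

    Samples with depth below ``min_depth`` or outside the field-of-view bound
    are NaN (marker lost); trackers skip them.
    """
    camera = camera if camera is not None else CameraModel()
    noise = noise if noise is not None else NoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed + 1)
    idx = np.arange(0, truth.n_samples, camera.rate_divisor)
    wrist = truth.wrist[idx]
    inv = camera.pose.inverse()
    p_cam = inv.apply(wrist)
    out = np.full((idx.size, 2), np.nan)
    ok = p_cam[:, 2] > camera.min_depth
    out[ok] = p_cam[ok, :2] / p_cam[ok, 2:3]
    visible = ok.copy()
    visible[ok] = np.max(np.abs(out[ok]), axis=1) <= camera.max_coord
    out[~visible] = np.nan
    if noise.camera_sigma > 0:
        out = out + noise.camera_sigma * rng.standard_normal(out.shape)
    return truth.t[idx], out


def perturb_calibration(
    mounting: SensorMounting, angle_deg: float, seed: int = 0
) -> SensorMounting:
    """Rotate every mounting rotation by a random axis, fixed-angle error."""
    if angle_deg < 0:
        raise ValueError("perturbation angle must be non-negative")
    if angle_deg == 0:
        return mounting
    rng = np.random.default_rng(seed)
    rot = {}
    for name, R in mounting.rotation.items():
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        rot[name] = R @ rotation_about_axis(axis, np.deg2rad(angle_deg))
    return replace(mounting, rotation=rot, lever_arm=dict(mounting.lever_arm))
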