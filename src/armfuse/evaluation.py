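"""Comparison protocol: reference-pose alignment of estimated against
reference wrist trajectories, the accuracy index E and correlation index C,
per-cycle breakdown, and the cross-method report.

Estimated and reference trajectories live in different frames (the chest
frame vs. the optical-capture frame in the original protocol).  Both series
are first translated so the N-pose reference sample is the origin; the
residual rotation is then the proper orthogonal Procrustes solution mapping
the estimate onto the reference, after which

* ``E`` — mean Euclidean distance per sample (reported in millimetres),
* ``C`` — Pearson correlation, computed per axis on centered coordinates
  and averaged over the axes that carry signal (axes with negligible
  reference variance are excluded; per-axis values are retained).

The alignment absorbs any constant rotation between the frames, so the
reported E underestimates each method's absolute error; it is a fair
*comparative* measure between methods, not an absolute one.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arm_model import default_arm_chain
from .chain_filters import method4_track, method5_track
from .estimators import FREE_SEGMENT_METHODS, TrackerResult, track_free_segments
from .synthetic import (
    CameraModel,
    GroundTruth,
    MotionScript,
    NoiseModel,
    default_mounting,
    generate_trajectory,
    synthesize_imu,
)

__all__ = [
    "AlignmentResult",
    "EvalReport",
    "align",
    "accuracy_E",
    "correlation_C",
    "segment_cycles",
    "ComparisonConfig",
    "run_comparison",
    "track_any",
    "ALL_METHODS",
]

ALL_METHODS = (
    "method1",
    "method2",
    "method3_pure",
    "method3_perfect",
    "method4",
    "method5",
)

#: methods that exploit the kinematic chain / linear-acceleration model
CHAIN_METHODS = ("method3_perfect", "method4", "method5")
FREE_METHODS = ("method1", "method2", "method3_pure")


@dataclass
class AlignmentResult:
    """Procrustes alignment: rotation ``R`` maps the (offset-removed)
    estimate onto the reference; ``Z = R·Y`` is comparable against ``X``."""

    R: np.ndarray
    X: np.ndarray  # offset-removed reference
    Z: np.ndarray  # aligned estimate
    x_ref: np.ndarray  # reference-pose sample subtracted from the reference
    y_ref: np.ndarray  # reference-pose sample subtracted from the estimate


def _procrustes_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing ``Σ‖x_j − R y_j‖²`` (SVD closed form with
    determinant correction — reflections excluded)."""
    B = X.T @ Y  # 3x3 cross-covariance
    if np.linalg.matrix_rank(B, tol=1e-12) < 2:
        warnings.warn("rank-deficient cross-covariance in alignment; "
                      "rotation may be poorly determined", stacklevel=3)
    U, _s, Vt = np.linalg.svd(B)
    D = np.diag([1.0, 1.0, np.linalg.det(U) * np.linalg.det(Vt)])
    return U @ D @ Vt


def align(reference, estimate, ref_pose_reference, ref_pose_estimate) -> AlignmentResult:
    """Translate both series to their N-pose reference samples, then rotate
    the estimate onto the reference (orthogonal Procrustes over proper
    rotations).  The residual ``Σ‖Z − X‖²`` is minimal over all rotations,
    so aligning cannot increase the error."""
    X = np.asarray(reference, float) - np.asarray(ref_pose_reference, float)
    Y = np.asarray(estimate, float) - np.asarray(ref_pose_estimate, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("reference and estimate must be matching (N,3) series")
    R = _procrustes_rotation(X, Y)
    return AlignmentResult(R, X, Y @ R.T, np.asarray(ref_pose_reference, float), np.asarray(ref_pose_estimate, float))


def accuracy_E(X, Z) -> float:
    """Mean per-sample Euclidean distance, in millimetres."""
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    if X.shape != Z.shape or len(X) < 1:
        raise ValueError("series must have equal non-zero length")
    return float(np.mean(np.linalg.norm(Z - X, axis=-1)) * 1e3)


def correlation_C(X, Z, axis_var_floor: float = 1e-12) -> tuple[float, np.ndarray]:
    """Pearson correlation of two 3-D series.

    Computed per axis on centered coordinates; the headline value averages
    the axes whose *reference* variance exceeds ``axis_var_floor`` times the
    largest axis variance (a single-DoF movement leaves one or two axes
    signal-free).  Returns ``(mean, per-axis values)``; axes without signal
    are NaN in the per-axis vector.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    if X.shape != Z.shape:
        raise ValueError("series must have equal shape")
    if X.ndim == 1:
        X = X[:, None]
        Z = Z[:, None]
    Xc = X - X.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    vx = np.mean(Xc**2, axis=0)
    vz = np.mean(Zc**2, axis=0)
    if np.all(vx <= 0) or np.all(vz <= 0):
        raise ValueError("zero-variance series: correlation undefined")
    out = np.full(X.shape[1], np.nan)
    keep = vx > axis_var_floor * vx.max()
    ok = keep & (vz > 0)
    out[ok] = np.mean(Xc[:, ok] * Zc[:, ok], axis=0) / np.sqrt(vx[ok] * vz[ok])
    return float(np.nanmean(out[keep])), out


def segment_cycles(truth: GroundTruth) -> list[tuple[int, int]]:
    """Cycle intervals (sample index ranges) of the scripted movement; empty
    with a warning if the trajectory is not periodic (zero amplitude)."""
    b = truth.cycle_bounds
    if b.size < 2:
        warnings.warn("trajectory has no cycles", stacklevel=2)
        return []
    return [(int(b[i]), int(b[i + 1])) for i in range(b.size - 1)]


# ---------------------------------------------------------------------------
# cross-method comparison
# ---------------------------------------------------------------------------

def track_any(method: str, stream, chain, mounting=None, use_camera: bool = True, params=None):
    """Dispatch a method name to its tracking harness."""
    if method in FREE_SEGMENT_METHODS:
        return track_free_segments(stream, chain, method, mounting, params=params)
    if method == "method4":
        return method4_track(stream, chain, mounting, params=params, use_camera=use_camera)
    if method == "method5":
        return method5_track(stream, chain, mounting, params=params)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ComparisonConfig:
    """Protocol of the cross-method run.

    Every movement runs the full 7-slow + 2-fast cycle script; the elbow
    movement additionally feeds the per-cycle table.  The static lead-in
    doubles as the N-pose alignment hold.
    """

    movements: tuple[str, ...] = ("EFE", "SFE", "SAA")
    methods: tuple[str, ...] = ALL_METHODS + ("strapdown",)
    seeds: tuple[int, ...] = (0,)
    noise: NoiseModel | None = None  # template; per-run seed overrides
    cycles: dict = field(
        default_factory=lambda: {"EFE": (7, 2), "SFE": (7, 2), "SAA": (7, 2)}
    )
    amplitudes: dict = field(default_factory=dict)  # per-movement override (rad)
    use_camera: bool = True
    per_cycle_movement: str = "EFE"


@dataclass
class EvalReport:
    """Per method × movement × seed accuracy/correlation plus the per-cycle
    table for the selected movement."""

    table: pd.DataFrame  # columns: movement, method, seed, E_mm, C, C_x, C_y, C_z
    cycles: pd.DataFrame  # columns: method, seed, cycle, pace, E_mm, C
    meta: dict

    def summary(self) -> pd.DataFrame:
        """Median over seeds, methods × movements."""
        return (
            self.table.groupby(["movement", "method"])
            .agg(E_mm=("E_mm", "median"), C=("C", "median"))
            .reset_index()
        )

    def to_markdown(self) -> str:
        buf = io.StringIO()
        s = self.summary().pivot(index="method", columns="movement")
        buf.write("# Cross-method comparison (median over seeds)\n\n")
        buf.write(s.to_string(float_format=lambda v: f"{v:.2f}"))
        buf.write("\n\n# Per-cycle E (mm), movement " + self.meta["per_cycle_movement"] + "\n\n")
        if len(self.cycles):
            pc = (
                self.cycles.groupby(["method", "cycle", "pace"])["E_mm"]
                .median()
                .reset_index()
                .pivot(index="cycle", columns="method", values="E_mm")
            )
            buf.write(pc.to_string(float_format=lambda v: f"{v:.2f}"))
        buf.write("\n")
        return buf.getvalue()


def _evaluate_result(truth: GroundTruth, res: TrackerResult, lead_samples: int):
    """Align on the lead-in hold, then score the movement part."""
    ref_pose = truth.wrist[:lead_samples].mean(axis=0) if lead_samples else truth.wrist[0]
    est_pose = res.wrist[:lead_samples].mean(axis=0) if lead_samples else res.wrist[0]
    al = align(truth.wrist, res.wrist, ref_pose, est_pose)
    E = accuracy_E(al.X, al.Z)
    try:
        C, C_axes = correlation_C(al.X, al.Z)
    except ValueError:  # static reference: correlation undefined
        C, C_axes = np.nan, np.full(3, np.nan)
    return al, E, C, C_axes


def run_comparison(config: ComparisonConfig | None = None, chain=None) -> EvalReport:
    """Simulate → track → align → score the full method × movement grid.

    Deterministic given the seed list: each (movement, seed) cell synthesizes
    one stream that all methods consume.  Failures are recorded per cell and
    the run continues.
    """
    config = config or ComparisonConfig()
    chain = chain or default_arm_chain()
    mounting = default_mounting()
    noise_template = config.noise or NoiseModel()
    rows = []
    cycle_rows = []
    errors = []

    for movement in config.movements:
        slow, fast = config.cycles.get(movement, (7, 2))
        script = MotionScript(
            movement,
            amplitude=config.amplitudes.get(movement),
            slow_cycles=slow,
            fast_cycles=fast,
        )
        truth = generate_trajectory(script, chain)
        lead = int(round(script.lead_in / (truth.t[1] - truth.t[0])))
        intervals = segment_cycles(truth)
        for seed in config.seeds:
            noise = NoiseModel(
                gyro_sigma=noise_template.gyro_sigma,
                gyro_bias=noise_template.gyro_bias,
                accel_sigma=noise_template.accel_sigma,
                mag_sigma=noise_template.mag_sigma,
                camera_sigma=noise_template.camera_sigma,
                mag_disturbance=noise_template.mag_disturbance,
                seed=int(seed),
            )
            stream = synthesize_imu(truth, mounting, noise, camera=CameraModel())
            for method in config.methods:
                try:
                    res = track_any(method, stream, chain, mounting, use_camera=config.use_camera)
                    al, E, C, C_axes = _evaluate_result(truth, res, lead)
                except Exception as exc:  # record and continue
                    errors.append({"movement": movement, "method": method, "seed": seed, "error": repr(exc)})
                    continue
                rows.append(
                    {
                        "movement": movement, "method": method, "seed": seed,
                        "E_mm": E, "C": C,
                        "C_x": C_axes[0], "C_y": C_axes[1], "C_z": C_axes[2],
                    }
                )
                if movement == config.per_cycle_movement:
                    for c, (i0, i1) in enumerate(intervals, start=1):
                        pace = "slow" if c <= slow else "fast"
                        Ec = accuracy_E(al.X[i0:i1], al.Z[i0:i1])
                        try:
                            Cc, _ = correlation_C(al.X[i0:i1], al.Z[i0:i1])
                        except ValueError:
                            Cc = np.nan
                        cycle_rows.append(
                            {"method": method, "seed": seed, "cycle": c, "pace": pace, "E_mm": Ec, "C": Cc}
                        )

    table = pd.DataFrame(rows)
    cycles = pd.DataFrame(cycle_rows)
    meta = {
        "seeds": list(config.seeds),
        "movements": list(config.movements),
        "methods": list(config.methods),
        "per_cycle_movement": config.per_cycle_movement,
        "errors": errors,
        "noise": {
            "gyro_sigma": noise_template.gyro_sigma,
            "gyro_bias": noise_template.gyro_bias,
            "accel_sigma": noise_template.accel_sigma,
            "mag_sigma": noise_template.mag_sigma,
            "camera_sigma": noise_template.camera_sigma,
        },
    }
    return EvalReport(table, cycles, meta)
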