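"""Persistence and configuration: stream/result CSV and HDF5 containers,
run configuration with schema validation, provenance headers, and the
miniature deterministic fixture bundles used by the test suite.

Wire formats are pinned for bit-exact fixtures: comma-separated CSV with a
header row, UTF-8, '.' decimal, column names suffixed with units, floats
rendered with ``%.17g`` (lossless for float64), provenance as leading
``#`` comment lines.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arm_model import KinematicChain, default_arm_chain
from .estimators import TrackerResult
from .evaluation import ComparisonConfig
from .synthetic import (
    CameraModel,
    ImuStream,
    MotionScript,
    NoiseModel,
    generate_trajectory,
    synthesize_imu,
)

__all__ = [
    "ConfigError",
    "Provenance",
    "write_streams",
    "read_streams",
    "write_result",
    "load_run_config",
    "make_fixtures",
]

_FLOAT_FMT = "%.17g"  # lossless float64 round trip, deterministic text

_IMU_COLUMNS = [
    "time_s", "segment",
    "ax_mps2", "ay_mps2", "az_mps2",
    "gx_rads", "gy_rads", "gz_rads",
    "mx_norm", "my_norm", "mz_norm",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content (CLI exit code 2)."""


@dataclass
class Provenance:
    """Stamped into every output file header."""

    seed: int | None = None
    config_hash: str | None = None
    version: str = __version__

    def header_lines(self) -> list[str]:
        return [
            f"# armfuse-version: {self.version}",
            f"# seed: {self.seed}",
            f"# config-hash: {self.config_hash}",
        ]


def config_hash(obj) -> str:
    return hashlib.sha256(
        yaml.safe_dump(obj, sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------

def write_streams(stream: ImuStream, path, provenance: Provenance | None = None) -> None:
    """Persist a stream losslessly; format chosen by suffix (.csv or .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(stream, path, provenance)
        return
    frames = []
    for name in stream.segments:
        df = pd.DataFrame(
            np.column_stack([stream.t, stream.accel[name], stream.gyro[name], stream.mag[name]]),
            columns=["time_s"] + _IMU_COLUMNS[2:],
        )
        df.insert(1, "segment", name)
        frames.append(df)
    if stream.camera is not None:
        cam = pd.DataFrame(
            np.column_stack([stream.camera_t, stream.camera]),
            columns=["time_s", "cam_x_norm", "cam_y_norm"],
        )
        cam.insert(1, "segment", "camera")
        frames.append(cam)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in (provenance or Provenance()).header_lines():
            fh.write(line + "\n")
        fh.write(f"# rate-hz: {stream.rate_hz:.12g}\n")
        out.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_h5(stream: ImuStream, path: Path, provenance: Provenance | None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = stream.rate_hz
        for k, v in asdict(provenance or Provenance()).items():
            f.attrs[f"provenance_{k}"] = "" if v is None else str(v)
        f.create_dataset("t", data=stream.t)
        g = f.create_group("imu")
        for name in stream.segments:
            sg = g.create_group(name)
            sg.create_dataset("accel", data=stream.accel[name])
            sg.create_dataset("gyro", data=stream.gyro[name])
            sg.create_dataset("mag", data=stream.mag[name])
        if stream.camera is not None:
            c = f.create_group("camera")
            c.create_dataset("t", data=stream.camera_t)
            c.create_dataset("xy", data=stream.camera)


def read_streams(path) -> ImuStream:
    """Read a stream written by :func:`write_streams` (CSV or HDF5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("time_s", "segment") if c not in df.columns]
    if missing:
        raise ConfigError(f"stream file missing columns {missing}")
    accel, gyro, mag = {}, {}, {}
    t = None
    cam_t = cam = None
    for name, sub in df.groupby("segment", sort=False):
        if name == "camera":
            cam_t = sub["time_s"].to_numpy()
            cam = sub[["cam_x_norm", "cam_y_norm"]].to_numpy()
            continue
        missing = [c for c in _IMU_COLUMNS[2:] if c not in sub.columns]
        if missing:
            raise ConfigError(f"segment {name!r} missing columns {missing}")
        ts = sub["time_s"].to_numpy()
        dt = np.diff(ts)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            bad = int(np.argmax(np.abs(dt - np.median(dt))))
            raise ConfigError(
                f"non-uniform sampling for segment {name!r} at sample {bad + 1}"
            )
        t = ts
        accel[name] = sub[["ax_mps2", "ay_mps2", "az_mps2"]].to_numpy()
        gyro[name] = sub[["gx_rads", "gy_rads", "gz_rads"]].to_numpy()
        mag[name] = sub[["mx_norm", "my_norm", "mz_norm"]].to_numpy()
    if t is None:
        raise ConfigError("stream file holds no IMU rows")
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 100.0
    return ImuStream(t, accel, gyro, mag, camera_t=cam_t, camera=cam, rate_hz=rate)


def _read_h5(path: Path) -> ImuStream:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["t"][:]
        accel, gyro, mag = {}, {}, {}
        for name in f["imu"]:
            accel[name] = f["imu"][name]["accel"][:]
            gyro[name] = f["imu"][name]["gyro"][:]
            mag[name] = f["imu"][name]["mag"][:]
        cam_t = cam = None
        if "camera" in f:
            cam_t = f["camera"]["t"][:]
            cam = f["camera"]["xy"][:]
        return ImuStream(t, accel, gyro, mag, camera_t=cam_t, camera=cam, rate_hz=float(f.attrs["rate_hz"]))


def write_result(result: TrackerResult, path, provenance: Provenance | None = None) -> None:
    """TrackerResult CSV: timestamp, per-segment quaternion wxyz, wrist xyz,
    and joint angles (rad) for the chain filters."""
    path = Path(path)
    data = {"time_s": result.t}
    for name, q in result.quaternions.items():
        for i, c in enumerate("wxyz"):
            data[f"{name}_q{c}"] = q[:, i]
    for i, c in enumerate("xyz"):
        data[f"wrist_{c}_m"] = result.wrist[:, i]
    if result.joint_angles is not None:
        for i in range(result.joint_angles.shape[1]):
            data[f"q{i}_rad"] = result.joint_angles[:, i]
    df = pd.DataFrame(data)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in (provenance or Provenance()).header_lines():
            fh.write(line + "\n")
        fh.write(f"# method: {result.method}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_NOISE_KEYS = {
    "gyro_sigma", "gyro_bias", "accel_sigma", "mag_sigma", "camera_sigma", "seed",
}
_CONFIG_KEYS = {
    "chain", "movements", "methods", "seeds", "noise", "cycles",
    "use_camera", "per_cycle_movement", "out_dir",
}


def load_run_config(path) -> tuple[ComparisonConfig, KinematicChain, dict]:
    """Validated comparison configuration from YAML; unknown keys rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    noise_cfg = raw.get("noise", {})
    if not isinstance(noise_cfg, dict):
        raise ConfigError("'noise' must be a mapping")
    unknown = set(noise_cfg) - _NOISE_KEYS
    if unknown:
        raise ConfigError(f"unknown noise keys: {sorted(unknown)}")
    try:
        noise = NoiseModel(**noise_cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid noise model: {exc}") from exc

    chain_cfg = raw.get("chain")
    if chain_cfg is None:
        chain = default_arm_chain()
    elif isinstance(chain_cfg, str):
        with open(chain_cfg, "r", encoding="utf-8") as fh:
            chain = KinematicChain.from_config(yaml.safe_load(fh))
    else:
        chain = KinematicChain.from_config(chain_cfg)

    kwargs = {}
    for key in ("movements", "methods", "seeds"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "cycles" in raw:
        kwargs["cycles"] = {k: tuple(v) for k, v in raw["cycles"].items()}
    if "use_camera" in raw:
        kwargs["use_camera"] = bool(raw["use_camera"])
    if "per_cycle_movement" in raw:
        kwargs["per_cycle_movement"] = str(raw["per_cycle_movement"])
    try:
        config = ComparisonConfig(noise=noise, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid comparison config: {exc}") from exc
    return config, chain, raw


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0, out_dir=None) -> dict:
    """Miniature deterministic bundles (2 s at 100 Hz) for EFE/SFE/SAA.

    Returns ``{movement: {"truth": GroundTruth, "stream": ImuStream}}`` and,
    if ``out_dir`` is given, writes one stream CSV and one truth CSV per
    movement.  Regenerating with the same seed is byte-identical.
    """
    out = {}
    for i, movement in enumerate(("EFE", "SFE", "SAA")):
        script = MotionScript(
            movement, slow_cycles=1, fast_cycles=0, slow_period=1.5, lead_in=0.5
        )
        truth = generate_trajectory(script)
        noise = NoiseModel(seed=seed * 31 + i)
        stream = synthesize_imu(truth, noise=noise, camera=CameraModel())
        out[movement] = {"truth": truth, "stream": stream}
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            prov = Provenance(seed=seed, config_hash=config_hash({"movement": movement, "seed": seed}))
            write_streams(stream, out_dir / f"{movement.lower()}_stream.csv", prov)
            df = pd.DataFrame(
                np.column_stack([truth.t, truth.Q, truth.wrist]),
                columns=["time_s"]
                + [f"{n}_rad" for n in truth.chain.joint_names]
                + ["wrist_x_m", "wrist_y_m", "wrist_z_m"],
            )
            with open(out_dir / f"{movement.lower()}_truth.csv", "w", encoding="utf-8", newline="\n") as fh:
                for line in prov.header_lines():
                    fh.write(line + "\n")
                df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return out
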