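"""On-disk dataset format, checkpoints and experiment configuration.

A dataset directory holds one sub-directory per subject, each with one CSV
per trial plus a ``metadata.json``:

* trial CSV columns — ``cam{1,2}_{joint}_{x,y}`` (44 height-normalized,
  mid-hip-centered video channels), ``imu{1..8}_{acc,gyr}_{x,y,z}`` (48 IMU
  channels), and the five targets ``kam, kfm, grf_ml, grf_v, grf_ap``.
  Simulated exports additionally carry the noise-free ground truth
  (``true_{joint}_{x,y,z}``, ``truevel_{joint}_{x,y,z}``,
  ``trueacc_{site}_{x,y,z}``); real exports may omit these.
* metadata — subject id, height (m), mass (kg), sampling rate, the
  generator seed and config hash, per-trial gait frequencies, and the
  subject's true forward-model coefficients when simulated.

Columns are read by name, so column order on disk is irrelevant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, SchemaError
from .models import ModelConfig, build_variant
from .synthetic import (DEFAULT_JOINTS, IMU_SITES, KINETIC_COMPONENTS,
                        SimConfig, SubjectRecording, Trial)
from .transfer import KDConfig, TrainConfig

__all__ = [
    "ExperimentConfig",
    "camera_columns",
    "imu_columns",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "config_hash",
]


def camera_columns() -> list[str]:
    cols = []
    for joint in DEFAULT_JOINTS:
        for cam in (1, 2):
            for axis in ("x", "y"):
                cols.append(f"cam{cam}_{joint}_{axis}")
    return cols


def imu_columns() -> list[str]:
    cols = []
    for i in range(1, len(IMU_SITES) + 1):
        for kind in ("acc", "gyr"):
            for axis in ("x", "y", "z"):
                cols.append(f"imu{i}_{kind}_{axis}")
    return cols


def _truth_columns() -> tuple[list[str], list[str], list[str]]:
    pos = [f"true_{j}_{a}" for j in DEFAULT_JOINTS for a in "xyz"]
    vel = [f"truevel_{j}_{a}" for j in DEFAULT_JOINTS for a in "xyz"]
    acc = [f"trueacc_{s}_{a}" for s in IMU_SITES for a in "xyz"]
    return pos, vel, acc


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce an experiment."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    kd: KDConfig = dataclasses.field(default_factory=KDConfig)
    stride: int | None = None      # window stride; None = non-overlapping
    max_folds: int | None = None   # limit LOSO folds (smoke profiles)
    variants: tuple[str, ...] = () # extra no-KT variants to train per fold
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = SimConfig(**_listfix(d.get("sim", {}),
                                   tuple_keys=("gait_frequency_range",)))
        model = ModelConfig(**_listfix(d.get("model", {}),
                                       tuple_keys=("mfm_submodules",)))
        train = TrainConfig(**d.get("train", {}))
        kd = KDConfig(**d.get("kd", {}))
        return cls(sim=sim, model=model, train=train, kd=kd,
                   stride=d.get("stride"), max_folds=d.get("max_folds"),
                   variants=tuple(d.get("variants", ())),
                   seed=int(d.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _listfix(d: dict, tuple_keys=()) -> dict:
    d = dict(d)
    for k in tuple_keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def config_hash(cfg) -> str:
    """Stable short hash of a config (dataclass or dict)."""
    if dataclasses.is_dataclass(cfg):
        cfg = dataclasses.asdict(cfg)
    payload = json.dumps(_tuples_to_lists(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# dataset save / load
# ---------------------------------------------------------------------------

def save_dataset(recordings: list[SubjectRecording], out_dir: str | Path,
                 sim_config: SimConfig | None = None) -> Path:
    """Write the documented directory layout; returns the dataset root."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cam_cols, imu_cols = camera_columns(), imu_columns()
    pos_cols, vel_cols, acc_cols = _truth_columns()
    for rec in recordings:
        subj_dir = root / rec.subject_id
        subj_dir.mkdir(exist_ok=True)
        for i, trial in enumerate(rec.trials):
            T = trial.camera.shape[0]
            frame = {}
            cam_flat = trial.camera.reshape(T, -1)
            for c, col in enumerate(cam_cols):
                frame[col] = cam_flat[:, c]
            for s in range(len(IMU_SITES)):
                for a, axis in enumerate("xyz"):
                    frame[f"imu{s + 1}_acc_{axis}"] = trial.imu_acc[:, s, a]
                    frame[f"imu{s + 1}_gyr_{axis}"] = trial.imu_gyr[:, s, a]
            for k, col in enumerate(KINETIC_COMPONENTS):
                frame[col] = trial.kinetics[:, k]
            if trial.true_positions is not None:
                tp = trial.true_positions.reshape(T, -1)
                tv = trial.true_velocities.reshape(T, -1)
                ta = trial.true_accelerations.reshape(T, -1)
                for c, col in enumerate(pos_cols):
                    frame[col] = tp[:, c]
                for c, col in enumerate(vel_cols):
                    frame[col] = tv[:, c]
                for c, col in enumerate(acc_cols):
                    frame[col] = ta[:, c]
            # %.17g keeps every float64 bit-exact through the text format
            pd.DataFrame(frame).to_csv(subj_dir / f"trial_{i:03d}.csv",
                                       index=False, float_format="%.17g")
        meta = {
            "subject_id": rec.subject_id,
            "height": rec.height,
            "mass": rec.mass,
            "sampling_rate": (sim_config.sampling_rate if sim_config
                              else 100.0),
            "seed": sim_config.seed if sim_config else None,
            "config_hash": config_hash(sim_config) if sim_config else None,
            "n_trials": len(rec.trials),
            "gait_frequencies": [t.gait_frequency for t in rec.trials],
            "forward_coefficients": {
                k: v.tolist() for k, v in rec.forward_coefficients.items()
            } if rec.forward_coefficients else None,
        }
        (subj_dir / "metadata.json").write_text(json.dumps(meta, indent=1))
    return root


def load_dataset(data_dir: str | Path) -> list[SubjectRecording]:
    """Load a dataset directory, validating the schema.

    Video channels are checked for the mid-hip-origin invariant (the mean
    of the left- and right-hip projections must vanish per frame).
    """
    root = Path(data_dir)
    if not root.is_dir():
        raise SchemaError(f"{root} is not a directory")
    subj_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not subj_dirs:
        raise SchemaError(f"no subject directories under {root}")
    cam_cols, imu_cols = camera_columns(), imu_columns()
    pos_cols, vel_cols, acc_cols = _truth_columns()
    required = cam_cols + imu_cols + list(KINETIC_COMPONENTS)
    recordings = []
    for subj_dir in subj_dirs:
        meta_path = subj_dir / "metadata.json"
        if not meta_path.exists():
            raise SchemaError(f"missing metadata.json in {subj_dir}")
        meta = json.loads(meta_path.read_text())
        trials = []
        for trial_path in sorted(subj_dir.glob("trial_*.csv")):
            df = pd.read_csv(trial_path, float_precision="round_trip")
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise SchemaError(
                    f"{trial_path} is missing columns {missing[:5]}"
                    f"{'...' if len(missing) > 5 else ''}"
                )
            T = len(df)
            camera = df[cam_cols].to_numpy().reshape(T, len(DEFAULT_JOINTS), 4)
            li = DEFAULT_JOINTS.index("l_hip")
            ri = DEFAULT_JOINTS.index("r_hip")
            origin = 0.5 * (camera[:, li, :] + camera[:, ri, :])
            if np.abs(origin).max() > 1e-6:
                raise SchemaError(
                    f"{trial_path}: video channels are not mid-hip-centered"
                )
            imu_acc = np.stack(
                [df[[f"imu{s + 1}_acc_{a}" for a in "xyz"]].to_numpy()
                 for s in range(len(IMU_SITES))], axis=1)
            imu_gyr = np.stack(
                [df[[f"imu{s + 1}_gyr_{a}" for a in "xyz"]].to_numpy()
                 for s in range(len(IMU_SITES))], axis=1)
            kinetics = df[list(KINETIC_COMPONENTS)].to_numpy()
            has_truth = all(c in df.columns for c in pos_cols)
            trials.append(Trial(
                true_positions=(df[pos_cols].to_numpy()
                                .reshape(T, len(DEFAULT_JOINTS), 3)
                                if has_truth else None),
                true_velocities=(df[vel_cols].to_numpy()
                                 .reshape(T, len(DEFAULT_JOINTS), 3)
                                 if has_truth else None),
                true_accelerations=(df[acc_cols].to_numpy()
                                    .reshape(T, len(IMU_SITES), 3)
                                    if has_truth else None),
                camera=camera, imu_acc=imu_acc, imu_gyr=imu_gyr,
                kinetics=kinetics,
                gait_frequency=(meta.get("gait_frequencies") or
                                [0.0] * 99)[len(trials)],
            ))
        if not trials:
            raise SchemaError(f"no trial CSVs in {subj_dir}")
        coeffs = meta.get("forward_coefficients")
        recordings.append(SubjectRecording(
            subject_id=meta["subject_id"],
            height=float(meta["height"]),
            mass=float(meta["mass"]),
            trials=trials,
            forward_coefficients={k: np.array(v) for k, v in coeffs.items()}
            if coeffs else None,
        ))
    recordings.sort(key=lambda r: r.subject_id)
    return recordings


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> None:
    """Save a model's weights, variant name and configuration."""
    arrays = model.state_arrays()
    meta = {
        "variant": model.spec.name,
        "model_config": _tuples_to_lists(dataclasses.asdict(model.cfg)),
        "config_hash": config_hash(model.cfg),
        "is_trained": bool(getattr(model, "is_trained", False)),
        "is_pretrained": bool(getattr(model, "is_pretrained", False)),
        "extra": extra or {},
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})


def load_checkpoint(path: str | Path):
    """Rebuild the model from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"arr_{i}"]
                  for i in range(len(data.files) - 1)]
    mc = meta["model_config"]
    mc["mfm_submodules"] = tuple(mc.get("mfm_submodules", ()))
    model = build_variant(meta["variant"], ModelConfig(**mc))
    model.load_state(arrays)
    model.is_trained = meta["is_trained"]
    model.is_pretrained = meta["is_pretrained"]
    model.eval()
    return model, meta
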