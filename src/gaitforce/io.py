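"""File formats: trial HDF5 layout, StepDataset HDF5, CSV import, configs.

Trial layout::

    /subjects/<subject_id>/trials/<condition_key>_<foot>/
        pressure  [T_p x 99] float32, kPa
        grf       [T_g x 3]  float32, N (treadmill frame)
        attrs: speed_mps, slope_deg, mass_kg, foot, fs_pressure, fs_grf
               (+ footstrike, idiosyncratic_gain, true_lag when known)

All writes are atomic (temp file + rename) and every JSON artifact embeds
the config hash and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import Condition, RawTrial, Step, StepDataset, SubjectMeta

__all__ = [
    "write_trials",
    "read_trials",
    "write_trial",
    "read_trial",
    "write_step_dataset",
    "read_step_dataset",
    "pressure_from_csv",
    "load_config",
    "config_hash",
    "atomic_write_json",
]

_REQUIRED_ATTRS = ("speed_mps", "slope_deg", "mass_kg", "foot", "fs_pressure", "fs_grf")


@contextmanager
def _atomic_h5(path: str, mode: str = "w"):
    """Write to a temp file in the same directory, rename on success."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def trial_key(trial: RawTrial) -> str:
    return f"{trial.condition.key}_{trial.foot}"


def _write_one(fh: h5py.File, trial: RawTrial) -> None:
    grp = fh.require_group(f"/subjects/{trial.subject.subject_id}/trials").create_group(
        trial_key(trial)
    )
    grp.create_dataset("pressure", data=trial.pressure.astype(np.float32))
    grp.create_dataset("grf", data=trial.grf.astype(np.float32))
    grp.attrs["speed_mps"] = trial.condition.speed
    grp.attrs["slope_deg"] = trial.condition.slope
    grp.attrs["mass_kg"] = trial.subject.mass
    grp.attrs["foot"] = trial.foot
    grp.attrs["fs_pressure"] = trial.fs_pressure
    grp.attrs["fs_grf"] = trial.fs_grf
    grp.attrs["footstrike"] = trial.subject.footstrike
    grp.attrs["idiosyncratic_gain"] = trial.subject.idiosyncratic_gain
    if trial.true_lag is not None:
        grp.attrs["true_lag"] = trial.true_lag


def _read_one(grp: h5py.Group, subject_id: str) -> RawTrial:
    for attr in _REQUIRED_ATTRS:
        if attr not in grp.attrs:
            raise KeyError(f"trial group {grp.name!r} is missing attribute '{attr}'")
    for name in ("pressure", "grf"):
        if name not in grp:
            raise KeyError(f"trial group {grp.name!r} is missing dataset '{name}'")
        if grp[name].dtype != np.float32:
            raise TypeError(f"dataset '{name}' must be float32")
    subject = SubjectMeta(
        subject_id=subject_id,
        mass=float(grp.attrs["mass_kg"]),
        footstrike=str(grp.attrs.get("footstrike", "rearfoot")),
        idiosyncratic_gain=float(grp.attrs.get("idiosyncratic_gain", 1.0)),
    )
    lag = grp.attrs.get("true_lag")
    return RawTrial(
        pressure=grp["pressure"][()],
        grf=grp["grf"][()],
        condition=Condition(float(grp.attrs["speed_mps"]), float(grp.attrs["slope_deg"])),
        subject=subject,
        foot=str(grp.attrs["foot"]),
        fs_pressure=float(grp.attrs["fs_pressure"]),
        fs_grf=float(grp.attrs["fs_grf"]),
        true_lag=int(lag) if lag is not None else None,
    )


def write_trials(path: str, trials: list[RawTrial]) -> None:
    with _atomic_h5(path) as fh:
        for trial in trials:
            _write_one(fh, trial)


def write_trial(path: str, trial: RawTrial) -> None:
    write_trials(path, [trial])


def read_trials(path: str) -> list[RawTrial]:
    out = []
    with h5py.File(path, "r") as fh:
        if "subjects" not in fh:
            raise KeyError(f"{path!r} has no /subjects group")
        for sid in fh["subjects"]:
            for key in fh[f"subjects/{sid}/trials"]:
                out.append(_read_one(fh[f"subjects/{sid}/trials/{key}"], sid))
    return out


def read_trial(path: str, subject_id: str, key: str) -> RawTrial:
    with h5py.File(path, "r") as fh:
        return _read_one(fh[f"subjects/{subject_id}/trials/{key}"], subject_id)


# ---------------------------------------------------------------------------
# step datasets


def write_step_dataset(path: str, dataset: StepDataset) -> None:
    pr, grf, meta = dataset.to_arrays()
    masses = np.array([s.mass if s.mass is not None else np.nan for s in dataset])
    with _atomic_h5(path) as fh:
        g = fh.create_group("steps")
        g.create_dataset("pr", data=pr)
        g.create_dataset("grf", data=grf)
        g.create_dataset("subject", data=meta["subject"].to_numpy(dtype="S16"))
        g.create_dataset("speed", data=meta["speed"].to_numpy())
        g.create_dataset("slope", data=meta["slope"].to_numpy())
        g.create_dataset("foot", data=meta["foot"].to_numpy(dtype="S8"))
        g.create_dataset("stance_duration", data=meta["stance_duration"].to_numpy())
        g.create_dataset("mass", data=masses)


def read_step_dataset(path: str) -> StepDataset:
    with h5py.File(path, "r") as fh:
        g = fh["steps"]
        pr = g["pr"][()]
        grf = g["grf"][()]
        subject = [s.decode() for s in g["subject"][()]]
        speed = g["speed"][()]
        slope = g["slope"][()]
        foot = [s.decode() for s in g["foot"][()]]
        dur = g["stance_duration"][()]
        mass = g["mass"][()]
    steps = [
        Step(
            pr=pr[i],
            grf_vert=grf[i, 0],
            grf_ap=grf[i, 1],
            condition=Condition(float(speed[i]), float(slope[i])),
            subject_id=subject[i],
            foot=foot[i],
            stance_duration=float(dur[i]),
            mass=None if np.isnan(mass[i]) else float(mass[i]),
        )
        for i in range(pr.shape[0])
    ]
    return StepDataset(steps)


def pressure_from_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Import a per-frame pressure CSV (time column + 99 sensor columns)."""
    df = pd.read_csv(path)
    if df.shape[1] != 100:
        raise ValueError(
            f"expected a time column plus 99 sensor columns, got {df.shape[1]}"
        )
    t = df.iloc[:, 0].to_numpy(dtype=float)
    frames = df.iloc[:, 1:].to_numpy(dtype=float)
    return t, frames


# ---------------------------------------------------------------------------
# configuration


_CONFIG_SCHEMA: dict[str, type | tuple] = {
    "paths": dict,
    "preprocess": dict,
    "model": dict,
    "training": dict,
    "evaluation": dict,
    "seed": int,
}


def load_config(path: str) -> dict[str, Any]:
    """YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _CONFIG_SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise TypeError(f"config key {key!r} must be {typ}")
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def atomic_write_json(path: str, payload: dict, cfg: dict | None = None) -> None:
    """JSON output with provenance (config hash) written atomically."""
    if cfg is not None:
        payload = {"config_hash": config_hash(cfg), **payload}
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".json.tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
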