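"""CSV/YAML/JSON readers and writers and run-config validation.

Conventions: angles are radians internally (degrees only at the CLI
boundary), lengths are meters internally and centimeters in parameter files
(the convention of printed muscle tables), signal CSVs carry a mandatory
header with a ``time_s`` column followed by one column per channel with a
unit suffix (``_mV``, ``_rad``, ``_Nm``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ExoParams, Trajectory
from .muscle import MuscleParams
from .signals import SignalTrace

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_muscles",
    "dump_muscles",
    "load_exo_params",
    "write_fit_report",
    "read_fit_report",
    "config_hash",
    "validate_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def read_signal_csv(path) -> SignalTrace:
    """Read a delimited signal file: ``time_s`` column then channel columns."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty or df.shape[0] < 2:
        raise ConfigError(f"{path}: empty or single-sample signal file")
    if "time_s" not in df.columns:
        raise ConfigError(f"{path}: missing mandatory time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ConfigError(f"{path}: non-uniform or non-increasing timestamps")
    chan = [c for c in df.columns if c != "time_s"]
    if not chan:
        raise ConfigError(f"{path}: no channel columns")
    vals = df[chan].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConfigError(f"{path}: NaN or infinite samples")
    labels = tuple(c.rsplit("_", 1)[0] for c in chan)
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    return SignalTrace(t=t, values=vals, fs=1.0 / float(dt[0]),
                       channel_labels=labels)


def write_signal_csv(trace: SignalTrace, path, unit="mV") -> None:
    vals = trace.values if trace.values.ndim == 2 else trace.values[:, None]
    labels = trace.channel_labels or tuple(
        f"ch{i}" for i in range(vals.shape[1]))
    df = pd.DataFrame({"time_s": trace.t})
    for i, lab in enumerate(labels):
        df[f"{lab}_{unit}"] = vals[:, i]
    df.to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("time_s", "theta_rad", "theta_dot_rad_s"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col}")
    return Trajectory.from_dataframe(df)


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_muscles(path) -> list[MuscleParams]:
    """Muscle parameter sets from YAML/JSON; lengths in cm (table units)."""
    data = _load_structured(path)
    entries = data["muscles"] if isinstance(data, dict) else data
    out = []
    for e in entries:
        e = dict(e)
        out.append(MuscleParams.from_cm(
            name=e.pop("name"),
            L_star_cm=e.pop("L_star_cm"),
            F_max=e.pop("F_max_N"),
            l_slack_cm=e.pop("l_slack_cm"),
            moment_arm=e.pop("moment_arm_m"),
            l_mt0_cm=e.pop("l_mt0_cm", None),
            **e,
        ))
    return out


def dump_muscles(muscles, path) -> None:
    entries = []
    for m in muscles:
        entries.append({
            "name": m.name, "channel": m.channel,
            "L_star_cm": round(float(m.L_star) * 100, 6),
            "l_slack_cm": round(float(m.l_slack) * 100, 6),
            "F_max_N": float(m.F_max),
            "moment_arm_m": float(m.moment_arm),
            "l_mt0_cm": round(float(m.l_mt0) * 100, 6),
        })
    Path(path).write_text(yaml.safe_dump({"muscles": entries},
                                         sort_keys=False))


def load_exo_params(path) -> ExoParams:
    data = _load_structured(path)
    d = data.get("exo", data)
    known = {"J", "B", "K", "m", "r_cm", "theta_r", "g"}
    bad = set(d) - known
    if bad:
        raise ConfigError(f"unknown exo parameter keys: {sorted(bad)}")
    return ExoParams(**d)


def config_hash(config: dict) -> str:
    """Stable short hash of a (nested) configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_KNOWN_TOP_KEYS = {
    "seed", "log_level", "paths", "signals", "muscle", "exo", "adjoint",
    "control", "benchmark", "generate", "identification",
}


def validate_config(config: dict) -> dict:
    """Reject unknown top-level keys and non-integer seeds; return config."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = config.get("seed", 0)
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise ConfigError("seed must be an integer")
    level = config.get("log_level", "info")
    if level not in ("debug", "info", "warning", "error"):
        raise ConfigError(f"invalid log_level {level!r}")
    return config


def write_fit_report(result, muscles, path, config=None, seed=0) -> None:
    """JSON fit report (parameters in table units) + loss-history CSV sidecar.

    ``result`` is a :class:`myoexo.adjoint.FitResult`; parameter entries are
    cm for the two lengths and N for F_max, one triple per muscle.
    """
    omega = np.asarray(result.omega_hat, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("non-finite fitted parameters")
    per_muscle = {}
    for i, m in enumerate(muscles):
        L, F, ls = omega[3 * i : 3 * i + 3]
        per_muscle[m.name] = {"L_star_cm": L * 100, "F_max_N": F,
                              "l_slack_cm": ls * 100}
    payload = {
        "parameters": per_muscle,
        "final_loss": float(result.loss_history[-1]),
        "iterations": int(result.n_iterations),
        "evals_per_iteration": float(np.mean(result.eval_counts)),
        "converged": bool(result.converged),
        "message": result.message,
        "seed": int(seed),
        "config_hash": config_hash(config or {}),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    side = path.with_suffix(".loss.csv")
    pd.DataFrame({
        "iteration": np.arange(result.loss_history.size),
        "loss": result.loss_history,
        "grad_inf_norm": result.grad_history,
        "loss_evaluations": result.eval_counts,
    }).to_csv(side, index=False)


def read_fit_report(path) -> dict:
    return json.loads(Path(path).read_text())
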