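"""Readers and writers for the package's on-disk formats.

* Trajectory CSV: columns ``time_h, tumor, normal, blood, total`` with a
  mandatory header, floats rendered as ``%.10g``.
* Observations CSV: columns ``time_h, value, compartment``.
* Parameter config: flat TOML or JSON with keys ``lambda_decay`` or
  ``half_life_h`` (mutually exclusive), ``elim``, ``beta_zx``, ``beta_zy``,
  ``beta_xz``, ``beta_yz``, ``n0``.
* Result reports (washout, fit): JSON.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, ObservationSet
from .model import KineticParameters, Trajectory, decay_constant
from .washout import WashoutResult

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_observations_csv",
    "read_observations_csv",
    "load_params_config",
    "dump_params_config",
    "write_washout_json",
    "write_fit_json",
]

_FLOAT_FORMAT = "%.10g"
_TRAJ_COLUMNS = ["time_h", "tumor", "normal", "blood", "total"]
_PARAM_KEYS = ("elim", "beta_zx", "beta_zy", "beta_xz", "beta_yz", "n0")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "time_h": traj.times,
            "tumor": traj.x,
            "normal": traj.y,
            "blood": traj.z,
            "total": traj.total,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trajectory_csv(path: str | Path, params: KineticParameters | None = None) -> Trajectory:
    frame = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks columns {missing}")
    return Trajectory(
        times=frame["time_h"].to_numpy(float),
        x=frame["tumor"].to_numpy(float),
        y=frame["normal"].to_numpy(float),
        z=frame["blood"].to_numpy(float),
        params=params,
    )


def write_observations_csv(obs: ObservationSet, path: str | Path) -> None:
    pd.DataFrame(
        {"time_h": obs.times, "value": obs.values, "compartment": obs.compartment}
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_observations_csv(path: str | Path) -> ObservationSet:
    frame = pd.read_csv(path)
    missing = [c for c in ("time_h", "value", "compartment") if c not in frame.columns]
    if missing:
        raise ValueError(f"observations CSV {path} lacks columns {missing}")
    compartments = frame["compartment"].unique()
    if len(compartments) != 1:
        raise ValueError(
            f"observations CSV must hold a single compartment, found {list(compartments)}"
        )
    return ObservationSet(
        times=frame["time_h"].to_numpy(float),
        values=frame["value"].to_numpy(float),
        compartment=str(compartments[0]),
    )


def load_params_config(path: str | Path) -> KineticParameters:
    """Read a parameter set from a flat TOML or JSON file.

    Exactly one of ``lambda_decay`` and ``half_life_h`` may be given
    (omitting both means no radioactive decay); unknown keys are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value table")
    known = set(_PARAM_KEYS) | {"lambda_decay", "half_life_h"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path} has unknown keys {sorted(unknown)}")
    if "lambda_decay" in raw and "half_life_h" in raw:
        raise ValueError("lambda_decay and half_life_h are mutually exclusive")
    kwargs = {k: float(raw[k]) for k in _PARAM_KEYS if k in raw}
    if "half_life_h" in raw:
        kwargs["lambda_decay"] = decay_constant(float(raw["half_life_h"]))
    elif "lambda_decay" in raw:
        kwargs["lambda_decay"] = float(raw["lambda_decay"])
    return KineticParameters(**kwargs)


def dump_params_config(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter set as flat JSON (readable back by load_params_config)."""
    payload = {
        "lambda_decay": params.lambda_decay,
        "elim": params.elim,
        "beta_zx": params.beta_zx,
        "beta_zy": params.beta_zy,
        "beta_xz": params.beta_xz,
        "beta_yz": params.beta_yz,
        "n0": params.n0,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _dump_json(payload: dict, path: str | Path | None) -> str:
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_washout_json(result: WashoutResult, path: str | Path | None = None) -> str:
    return _dump_json(result.to_dict(), path)


def write_fit_json(result: FitResult, path: str | Path | None = None) -> str:
    return _dump_json(result.to_dict(), path)


def conservation_residual(traj: Trajectory) -> float:
    """Max deviation of the total amount from n0*exp(-lambda*t).

    Meaningful as a conservation check when elimination is zero; with E > 0
    the total legitimately falls below the decay envelope.
    """
    if traj.params is None:
        raise ValueError("trajectory has no parameters")
    envelope = traj.params.n0 * np.exp(-traj.params.lambda_decay * traj.times)
    return float(np.max(np.abs(traj.total - envelope)))
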