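"""Configuration files and CSV interchange.

Configs are flat YAML or JSON records.  Either member of each derived
pair may be given -- ``tau_k`` or ``epsilon``, ``R_w`` or ``r`` -- and
unknown keys are rejected.  All floats are serialized at
repr-round-trip precision so write/read cycles are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .model import ModelParams, stationary_current
from .presets import PRESETS, preset

__all__ = [
    "load_config",
    "save_config",
    "params_to_dict",
    "params_from_dict",
    "steady_state_table",
    "write_csv",
]

_REQUIRED = ("tau_m", "R_I", "b")
_PAIRS = (("tau_k", "epsilon"), ("R_w", "r"))
_ALLOWED = set(_REQUIRED) | {"u_1"} | {k for pair in _PAIRS for k in pair}


def params_from_dict(d: dict) -> ModelParams:
    """Validate a flat config mapping and build :class:`ModelParams`."""
    if not isinstance(d, dict):
        raise ConfigError(f"config must be a mapping, got {type(d).__name__}")
    unknown = set(d) - _ALLOWED
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for key in _REQUIRED:
        if key not in d:
            raise ConfigError(f"missing required config key: {key}")
    kwargs = {k: d[k] for k in _REQUIRED}
    kwargs["u_1"] = d.get("u_1", 1.0)
    for absolute, ratio in _PAIRS:
        if absolute in d and ratio in d:
            raise ConfigError(f"give either {absolute} or {ratio}, not both")
        if absolute not in d and ratio not in d:
            raise ConfigError(f"missing config key: {absolute} (or {ratio})")
    for key, value in d.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"config key {key} must be a number, got {value!r}")
    tau_k = d["tau_k"] if "tau_k" in d else _ratio_to_abs(d, "epsilon", d["tau_m"])
    R_w = d["R_w"] if "R_w" in d else _ratio_to_abs(d, "r", d["R_I"])
    try:
        return ModelParams(tau_k=tau_k, R_w=R_w, **kwargs)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def _ratio_to_abs(d: dict, key: str, numerator: float) -> float:
    value = d[key]
    if not isinstance(value, (int, float)) or value <= 0:
        raise ConfigError(f"config key {key} must be a positive number, got {value!r}")
    return numerator / value


def load_config(source: Union[str, Path]) -> ModelParams:
    """Load parameters from a preset name or a YAML/JSON config file."""
    if isinstance(source, str) and source in PRESETS:
        return preset(source)
    path = Path(source)
    if not path.is_file():
        raise ConfigError(
            f"{source!r} is neither a preset ({', '.join(PRESETS)}) nor an existing file"
        )
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return params_from_dict(data)


def params_to_dict(p: ModelParams) -> dict:
    return {
        "tau_m": p.tau_m,
        "tau_k": p.tau_k,
        "R_I": p.R_I,
        "R_w": p.R_w,
        "b": p.b,
        "u_1": p.u_1,
    }


def save_config(p: ModelParams, path: Union[str, Path]) -> None:
    """Write a parameter set to YAML (or JSON by suffix), round-trip exact."""
    path = Path(path)
    d = params_to_dict(p)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def steady_state_table(
    p: ModelParams, u_min: float, u_max: float, n: int = 501
) -> pd.DataFrame:
    """Stationary current-voltage table over [u_min, u_max]."""
    u = np.linspace(u_min, u_max, n)
    return pd.DataFrame({"u": u, "I": stationary_current(u, p)})


def write_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """CSV export at 17-significant-digit (repr round-trip) precision."""
    df.to_csv(path, index=False, float_format="%.17g")
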