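"""Configuration validation, result serialization and provenance records.

Every experiment writes a CSV with a stable column order plus a JSON
metadata sidecar (effective configuration, its hash, package version,
timestamp), so reruns with the same configuration produce byte-identical
CSVs and an auditable trail.  Weight matrices can be persisted to ``.npz``
with a JSON sidecar carrying their generative parameters.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensembles import EnsembleParams, WeightMatrix

__all__ = [
    "ConfigError",
    "RunConfig",
    "COMMAND_SCHEMAS",
    "load_config",
    "write_results",
    "save_weight_matrix",
    "load_weight_matrix",
]


class ConfigError(ValueError):
    """Raised for schema violations in run configurations."""


def _positive(x: float) -> bool:
    return x > 0


def _tau_ok(x: float) -> bool:
    return -1.0 <= x <= 1.0


def _tau_grid_ok(xs: Any) -> bool:
    return hasattr(xs, "__iter__") and len(list(xs)) > 0 and all(
        -1.0 <= float(x) <= 1.0 for x in xs
    )


# field -> (python types, validator or None, default or REQUIRED)
REQUIRED = object()
_COMMON = {
    "seed": ((int,), lambda s: s >= 0, 0),
    "out": ((str, type(None)), None, None),
}
COMMAND_SCHEMAS: dict[str, dict[str, tuple]] = {
    "complexity": {
        **_COMMON,
        "geff": ((float, int, type(None)), None, None),
        "g": ((float, int, type(None)), None, None),
        "tau_grid": ((list, tuple), _tau_grid_ok, tuple(np.round(np.linspace(-0.99, 1.0, 41), 10))),
    },
    "spectrum": {
        **_COMMON,
        "geff": ((float, int, type(None)), None, None),
        "g": ((float, int, type(None)), None, None),
        "tau": ((float, int), _tau_ok, 0.0),
        "N": ((int,), lambda n: n >= 1, 1000),
    },
    "simulate": {
        **_COMMON,
        "geff": ((float, int, type(None)), None, None),
        "g": ((float, int, type(None)), None, None),
        "tau": ((float, int), _tau_ok, 0.0),
        "N": ((int,), lambda n: n >= 1, 500),
        "t_max": ((float, int), _positive, 200.0),
        "dt": ((float,), lambda d: 0 < d < 0.2, 0.05),
    },
    "sweep": {
        **_COMMON,
        "preset": ((str,), lambda p: p in ("dynamics", "pathlength"), REQUIRED),
    },
    "pathlen": {
        **_COMMON,
        "geff": ((float, int), _positive, 1.2),
        "tau_grid": ((list, tuple), _tau_grid_ok, (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)),
        "N": ((int,), lambda n: n >= 1, 300),
        "reps": ((int,), lambda r: r >= 1, 50),
        "t_max": ((float, int), _positive, 750.0),
    },
    "kacrice": {
        **_COMMON,
        "N": ((int,), lambda n: 1 <= n <= 100, 30),
        "g": ((float, int), _positive, 1.5),
        "tau": ((float, int), _tau_ok, 0.0),
        "reps": ((int,), lambda r: r >= 100, 1000),
    },
    "count": {
        **_COMMON,
        "N": ((int,), lambda n: n >= 1, 1),
        "g": ((float, int), _positive, 1.5),
        "tau": ((float, int), _tau_ok, 0.0),
        "reps": ((int,), lambda r: r >= 1, 1000),
    },
}


@dataclass(frozen=True)
class RunConfig:
    """A validated command plus its effective (defaults-filled) parameters."""

    command: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"command": self.command, **self.params}


def _coerce(name: str, value: Any, types: tuple) -> Any:
    if float in types and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, list):
        return tuple(value)
    return value


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
    command: str | None = None,
) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file and/or overrides.

    Flag-style ``overrides`` take precedence over file values.  Unknown
    keys, out-of-range values and missing required fields raise
    :class:`ConfigError` naming the offending field.  Defaults are filled
    so the returned configuration is fully explicit (audit trail).
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    cmd = command or data.pop("command", None)
    data.pop("command", None)
    if cmd not in COMMAND_SCHEMAS:
        raise ConfigError(
            f"unknown command {cmd!r}; expected one of {sorted(COMMAND_SCHEMAS)}"
        )
    schema = COMMAND_SCHEMAS[cmd]
    unknown = set(data) - set(schema)
    if unknown:
        raise ConfigError(f"unknown field(s) for command {cmd!r}: {sorted(unknown)}")
    params: dict[str, Any] = {}
    for name, (types, validator, default) in schema.items():
        if name in data:
            value = _coerce(name, data[name], types)
            if not isinstance(value, tuple(t for t in types)) and not (
                isinstance(value, tuple) and (list in types or tuple in types)
            ):
                raise ConfigError(
                    f"field {name!r}: expected {'/'.join(t.__name__ for t in types)}, "
                    f"got {type(value).__name__}"
                )
            if validator is not None and not validator(value):
                raise ConfigError(f"field {name!r}: value {value!r} out of range")
            params[name] = value
        elif default is REQUIRED:
            raise ConfigError(f"missing required field {name!r} for command {cmd!r}")
        else:
            params[name] = default
    # cross-field rules shared by gain-taking commands
    if "g" in params and "geff" in params:
        if (params["g"] is None) == (params["geff"] is None):
            raise ConfigError("exactly one of 'g' and 'geff' must be set")
        tau_vals = params.get("tau_grid", (params.get("tau", 0.0),))
        if params["geff"] is not None and any(float(t) == -1.0 for t in tau_vals):
            raise ConfigError("'geff' cannot be combined with tau = -1 (g undefined)")
    return RunConfig(command=cmd, params=params)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_results(
    table: pd.DataFrame,
    out_dir: str | Path,
    name: str,
    config: RunConfig | Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write a result table as CSV plus a JSON metadata sidecar.

    The CSV has a header and stable column order; identical inputs yield
    byte-identical CSVs.  The sidecar records the effective configuration,
    a hash of it, the package version and a timestamp, and the effective
    config is also echoed as YAML for round-tripping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise ConfigError(f"output directory {out_dir} is not writable")
    csv_path = out_dir / f"{name}.csv"
    table.to_csv(csv_path, index=False)
    cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config or {})
    cfg = _jsonable(cfg)
    cfg_blob = json.dumps(cfg, sort_keys=True).encode()
    meta = {
        "name": name,
        "config": cfg,
        "config_hash": hashlib.sha256(cfg_blob).hexdigest(),
        "package_version": __version__,
        "n_rows": int(len(table)),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    meta_path = out_dir / f"{name}.meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths = {"csv": csv_path, "meta": meta_path}
    if cfg:
        yaml_path = out_dir / f"{name}.config.yaml"
        yaml_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        paths["config"] = yaml_path
    return paths


def save_weight_matrix(W: WeightMatrix, path: str | Path) -> Path:
    """Persist a weight matrix as ``.npz`` with a JSON metadata sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, values=W.values)
    meta = {
        "N": W.params.N,
        "g": W.params.g,
        "tau": W.params.tau,
        "geff": W.params.geff,
        "seed": W.params.seed,
        "diagonal_policy": W.params.diagonal_policy,
        "realization_index": W.realization_index,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_weight_matrix(path: str | Path) -> WeightMatrix:
    """Load a weight matrix saved by :func:`save_weight_matrix`."""
    path = Path(path).with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    params = EnsembleParams(
        N=meta["N"], tau=meta["tau"], g=meta["g"], seed=meta["seed"],
        diagonal_policy=meta["diagonal_policy"],
    )
    with np.load(path) as data:
        values = data["values"]
    return WeightMatrix(values=values, params=params,
                        realization_index=meta["realization_index"])
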