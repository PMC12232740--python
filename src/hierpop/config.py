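"""YAML configuration handling and run provenance for the CLI."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import yaml

from .simulate import SimulationConfig


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def simulation_config(cfg: dict, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from the `simulation:` section plus overrides."""
    params = dict(cfg.get("simulation", {}))
    if "traits" in params:
        params["traits"] = tuple(params["traits"])
    if seed is not None:
        params["seed"] = int(seed)
    return SimulationConfig(**params)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_summary(cfg: dict, seed: int, extra: dict | None = None) -> dict:
    from . import __version__

    out = {
        "seed": int(seed),
        "config_hash": config_hash(cfg),
        "versions": {
            "hierpop": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        out.update(extra)
    return out


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
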