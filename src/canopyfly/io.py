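"""Configuration files and deterministic result output.

Configs are YAML mappings mirroring :class:`~canopyfly.engine.SimConfig`
field-for-field, with a nested ``sensing`` mapping (and a nested ``curve``
for the detection-probability coefficients). Every omitted field takes the
model's standard default, so an empty file is a valid config. Unknown keys
are rejected to catch typos. Output writing is byte-deterministic: fixed row
order, fixed float formatting, sorted JSON keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import List

import pandas as pd
import yaml

from .behaviour import DetectionCurve, SensingSpec
from .engine import RunResult, SimConfig

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Raised for schema violations in a configuration file."""


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    return data


def dict_to_config(data: dict) -> SimConfig:
    data = dict(_from_mapping(SimConfig, data or {}, "config"))
    sensing_data = dict(_from_mapping(SensingSpec, data.pop("sensing", {}) or {}, "sensing"))
    curve_data = _from_mapping(DetectionCurve, sensing_data.pop("curve", {}) or {}, "curve")
    try:
        sensing = SensingSpec(curve=DetectionCurve(**curve_data), **sensing_data)
        return SimConfig(sensing=sensing, **data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def load_config(path) -> SimConfig:
    """Parse and validate a YAML config file; defaults fill omitted fields."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return dict_to_config(data or {})


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_results(results: List[RunResult], out_dir, config: SimConfig) -> Path:
    """Write per-replicate region and cube CSVs plus a JSON manifest.

    Returns the manifest path. Re-running with identical inputs produces
    byte-identical files.
    """
    if not results:
        raise ValueError("results must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    totals = []
    for res in results:
        region_path = out_dir / f"replicate_{res.replicate_index:03d}_regions.csv"
        cube_path = out_dir / f"replicate_{res.replicate_index:03d}_cubes.csv"
        res.region_frame().to_csv(region_path, index=False, float_format=FLOAT_FORMAT)
        res.canopy.to_frame().to_csv(cube_path, index=False, float_format=FLOAT_FORMAT)
        files.extend([region_path.name, cube_path.name])
        totals.append(
            {
                "replicate": res.replicate_index,
                "total_visits": res.total_visits,
                "departures": res.departures,
            }
        )
    manifest = {
        "package": "canopyfly",
        "master_seed": config.master_seed,
        "config": config_to_dict(config),
        "config_hash": config_hash(config),
        "n_replicates": len(results),
        "replicates": totals,
        "files": files,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
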