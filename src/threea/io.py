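"""Configuration loading, result serialization, and run manifests.

Config files are YAML (JSON is a YAML subset and also parses).  The
``simulation`` section accepts either the long field names of
``SimulationParams`` or the conventional one-letter/zone symbols
(N, U, zr, zl, za, alpha, theta_max, sigma, dt, T, seed).  Missing keys take
the model defaults.

Every results directory written by :func:`write_results` contains CSV tables
(floats at 17 significant digits, so a read-back round-trips exactly), a
JSON metadata file with the full parameter snapshot and base seed, and a
manifest with SHA-256 checksums of every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .escape import KramersFit
from .observables import OrderParameterSeries
from .params import SimulationParams
from .protocols import HysteresisResult, SweepResult
from .sde import SDEHysteresisResult

__all__ = [
    "load_config",
    "write_results",
    "write_series_csv",
    "write_trajectory_csv",
    "RunManifest",
]

_VERSION = "0.1.0"
_FLOAT_FMT = "%.17g"

_SYMBOL_ALIASES = {
    "N": "n_fish",
    "U": "speed",
    "zr": "z_repulsion",
    "zl": "z_alignment",
    "za": "z_attraction",
    "alpha": "field_of_view",
    "theta_max": "max_turn",
    "sigma": "noise_sigma",
    "T": "total_time",
}


@dataclass(frozen=True)
class RunManifest:
    config: dict
    base_seed: int
    version: str
    checksums: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce_simulation(section: dict) -> SimulationParams:
    fields = {f.name for f in dataclasses.fields(SimulationParams)}
    kwargs = {}
    for key, value in section.items():
        name = _SYMBOL_ALIASES.get(key, key)
        if name not in fields:
            raise ValueError(f"unknown simulation parameter: {key!r}")
        kwargs[name] = value
    return SimulationParams(**kwargs)  # __post_init__ validates invariants


def load_config(path) -> dict:
    """Load and validate a config file.

    Returns a dict with key ``simulation`` holding a validated
    ``SimulationParams`` (an empty or absent section yields the defaults) and
    any other top-level sections passed through unchanged.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    out = dict(raw)
    out["simulation"] = _coerce_simulation(raw.get("simulation", {}) or {})
    return out


def write_series_csv(series: OrderParameterSeries, path) -> None:
    """Order-parameter series with header time,P,M,nnd_mean,nnd_sd."""
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trajectory_csv(states, path) -> None:
    """Long-format trajectory with header time,fish_id,x,y,z,px,py,pz."""
    rows = []
    for state in states:
        n = state.n_fish
        block = np.column_stack(
            [
                np.full(n, state.time),
                np.arange(n),
                state.positions,
                state.headings,
            ]
        )
        rows.append(block)
    frame = pd.DataFrame(
        np.vstack(rows),
        columns=["time", "fish_id", "x", "y", "z", "px", "py", "pz"],
    )
    frame["fish_id"] = frame["fish_id"].astype(int)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _result_tables(result) -> dict[str, pd.DataFrame]:
    if isinstance(result, SweepResult):
        tables = {"summary.csv": result.summary_frame()}
        if len(result.per_replicate):
            tables["per_replicate.csv"] = result.per_replicate
        return tables
    if isinstance(result, HysteresisResult):
        name = f"hysteresis_{result.direction}.csv"
        tables = {name: result.summary_frame()}
        if len(result.per_replicate):
            tables[f"per_replicate_{result.direction}.csv"] = result.per_replicate
        return tables
    if isinstance(result, SDEHysteresisResult):
        frame = pd.DataFrame({"r": result.r_values, "P_mean": result.p_means})
        return {f"sde_hysteresis_{result.direction}.csv": frame}
    if isinstance(result, KramersFit):
        frame = pd.DataFrame(
            {
                "prefactor": [result.prefactor],
                "sigma_collective": [result.sigma_collective],
                "zl_star": [result.zl_star if result.zl_star is not None else np.nan],
            }
        )
        return {"kramers_fit.csv": frame}
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_results(
    result, out_dir, base_seed: int, config: dict | None = None
) -> RunManifest:
    """Write a protocol result to ``out_dir``: CSV tables, JSON metadata, and
    a manifest with per-table SHA-256 checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = _result_tables(result)
    checksums = {}
    for name, frame in tables.items():
        path = out_dir / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        checksums[name] = _sha256(path)
    config_snapshot = _jsonable(config or {})
    metadata = {
        "base_seed": int(base_seed),
        "version": _VERSION,
        "config": config_snapshot,
        "result_type": type(result).__name__,
    }
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    manifest = RunManifest(
        config=config_snapshot,
        base_seed=int(base_seed),
        version=_VERSION,
        checksums=checksums,
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return manifest
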