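"""Configuration files, trajectory CSV round-trips and run manifests.

Configs are flat YAML (or JSON) mappings with a mandatory ``schema`` tag
(``grid`` or ``pathway``); absent keys take the published defaults and
unknown keys are rejected.  Trajectories travel as plain CSV with a
mandatory header, so every artefact is diff-able; each CLI command writes a
JSON manifest (command, config hash, seed, version, outputs, timestamp)
next to its outputs so any published table can be regenerated.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grid_abm import GridConfig, Trajectory
from .reaction_abm import MetabolicTrajectory, PathwayConfig

__all__ = [
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_metabolic_trajectory",
    "read_metabolic_trajectory",
    "write_manifest",
]

GRID_COLUMNS = ["k", "nutrient_rich", "prey", "predators", "u1", "u2"]
PATHWAY_COLUMNS = ["k", "S", "P", "Q", "R", "T",
                   "freeA", "freeE", "freeI", "freeO", "q"]

_SCHEMAS = {"grid": GridConfig, "pathway": PathwayConfig}


def load_config(path) -> Union[GridConfig, PathwayConfig]:
    """Read a config file; the ``schema`` tag selects the config type,
    missing keys take the published defaults, unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    schema = data.pop("schema", None)
    if schema not in _SCHEMAS:
        raise ValueError(
            f"config {path} needs a 'schema' key with value 'grid' or "
            f"'pathway', got {schema!r}"
        )
    cls = _SCHEMAS[schema]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys for schema {schema}: {sorted(unknown)}")
    return cls(**data)


def save_config(path, config: Union[GridConfig, PathwayConfig]) -> None:
    schema = "grid" if isinstance(config, GridConfig) else "pathway"
    payload = {"schema": schema, **dataclasses.asdict(config)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_trajectory(path, traj: Trajectory) -> None:
    """Grid trajectory CSV: one row per observation; ``u1, u2`` on row k are
    the controls applied during period k (zeros on the final row)."""
    n = len(traj)
    u = np.vstack([traj.controls, [[0, 0]]])
    df = pd.DataFrame(
        {
            "k": np.arange(n),
            "nutrient_rich": traj.a,
            "prey": traj.b,
            "predators": traj.c,
            "u1": u[:, 0],
            "u2": u[:, 1],
        }
    )
    df.to_csv(path, index=False)


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: empty trajectory (need at least the "
                         "initial observation)")
    return df


def read_trajectory(path) -> Trajectory:
    df = _read_csv(path, GRID_COLUMNS)
    for col in GRID_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.integer):
            raise ValueError(f"{path}: column {col} must be integer")
    return Trajectory(
        a=df["nutrient_rich"].to_numpy(),
        b=df["prey"].to_numpy(),
        c=df["predators"].to_numpy(),
        controls=df[["u1", "u2"]].to_numpy()[:-1],
    )


def write_metabolic_trajectory(path, traj: MetabolicTrajectory) -> None:
    n = len(traj)
    df = pd.DataFrame(
        {
            "k": np.arange(n),
            "S": traj.S, "P": traj.P, "Q": traj.Q, "R": traj.R, "T": traj.T,
            "freeA": traj.freeA, "freeE": traj.freeE,
            "freeI": traj.freeI, "freeO": traj.freeO,
            "q": np.concatenate([traj.q, [0.0]]),
        }
    )
    df.to_csv(path, index=False)


def read_metabolic_trajectory(path) -> MetabolicTrajectory:
    df = _read_csv(path, PATHWAY_COLUMNS)
    return MetabolicTrajectory(
        S=df["S"].to_numpy(), P=df["P"].to_numpy(), Q=df["Q"].to_numpy(),
        R=df["R"].to_numpy(), T=df["T"].to_numpy(),
        freeA=df["freeA"].to_numpy(), freeE=df["freeE"].to_numpy(),
        freeI=df["freeI"].to_numpy(), freeO=df["freeO"].to_numpy(),
        q=df["q"].to_numpy()[:-1],
    )


def write_manifest(out_path, command: str, config_hash: str = "", seed=None,
                   outputs=()) -> Path:
    """Write the reproducibility manifest next to ``out_path``."""
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "config_hash": config_hash,
        "seed": seed,
        "version": __version__,
        "outputs": [str(o) for o in outputs],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
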