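"""Tabular output, run manifests, and configuration files.

Every file the CLI writes is paired with a JSON manifest recording the
subcommand, the full parameter set, the seed and the package version —
enough to reproduce the output bit-exactly (deterministic runs) or
statistically (stochastic runs).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["write_results", "write_manifest", "write_json", "load_config", "SCHEMAS"]

#: documented CSV schemas, by name
SCHEMAS: dict[str, list[str]] = {
    "trajectory": ["time", "fX", "fY", "fZ", "coop_rate"],
    "basin_cells": ["fX0", "fY0", "fZ0", "attractor_label"],
    "abm_generations": ["generation", "coop_rate", "fX", "fY", "fZ", "mean_good"],
    "pip": ["E_resident", "E_invader", "sign_W"],
    "ess_scan": ["norm", "b_over_c", "E_star", "stability"],
    "empathy_agents": ["generation", "agent_id", "E"],
    "empathy_mean": ["replicate", "generation", "mean_E", "coop_rate"],
}


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass --force to overwrite")


def write_results(
    records: pd.DataFrame, schema: str, path, *, force: bool = False
) -> Path:
    """Write a CSV in one of the documented schemas (UTF-8, '.' decimals).

    The schema's columns must be present and come first; extra columns (for
    example a replicate index) are appended after them.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records missing schema columns {missing} for schema {schema!r}")
    path = Path(path)
    _check_overwrite(path, force)
    extra = [c for c in records.columns if c not in cols]
    path.parent.mkdir(parents=True, exist_ok=True)
    records[cols + extra].to_csv(path, index=False, encoding="utf-8")
    return path


def write_json(payload: dict, path, *, force: bool = False) -> Path:
    path = Path(path)
    _check_overwrite(path, force)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def write_manifest(
    subcommand: str, parameters: dict, seed, outputs: list, path, *, force: bool = False
) -> Path:
    """Record everything needed to re-create the paired outputs."""
    payload = {
        "subcommand": subcommand,
        "parameters": parameters,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(o) for o in outputs],
    }
    return write_json(payload, path, force=force)


def load_config(path) -> dict:
    """Load a flat YAML mapping of option values; {} when path is None."""
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    return {str(k).replace("-", "_"): v for k, v in cfg.items()}
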