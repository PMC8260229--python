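"""Validated CSV table IO and config handling.

Two headered, comma-separated table schemas are shared by the generators
and the analysis:

* ``assay``: ``experiment_id,scenario,replicate_id,n_pheromone,n_control,
  n_total_placed``
* ``timecourse``: ``experiment_id,replicate_id,hour,n_left_patch,
  new_at_pheromone,new_at_control``

Validation errors carry the 1-based data row and the offending column.
Round trips are exact: integer columns stay integers and the decimal
separator is always '.' regardless of locale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = ["SchemaError", "SCHEMAS", "read_table", "write_table",
           "read_config", "write_metadata", "config_from_mapping"]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


#: schema name -> (column, dtype kind) pairs; "int" columns must be
#: non-negative integers, "str" columns are labels
SCHEMAS: dict[str, dict[str, str]] = {
    "assay": {
        "experiment_id": "str",
        "scenario": "str",
        "replicate_id": "str",
        "n_pheromone": "int",
        "n_control": "int",
        "n_total_placed": "int",
    },
    "timecourse": {
        "experiment_id": "str",
        "replicate_id": "str",
        "hour": "int",
        "n_left_patch": "int",
        "new_at_pheromone": "int",
        "new_at_control": "int",
    },
}


def _validate(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    try:
        schema = SCHEMAS[schema_name]
    except KeyError:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} for schema {schema_name!r}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"unexpected columns {extra} for schema {schema_name!r}")
    df = df[list(schema)].copy()  # canonical column order
    for col, kind in schema.items():
        if kind != "int":
            continue
        values = df[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(
                f"column {col!r}, data row {row}: expected a non-negative "
                f"integer, got {values.iloc[row - 1]!r}"
            )
        df[col] = numeric.astype(np.int64)
    if schema_name == "assay" and len(df):
        over = df["n_pheromone"] + df["n_control"] > df["n_total_placed"]
        if over.any():
            row = int(np.flatnonzero(over.to_numpy())[0]) + 1
            raise SchemaError(
                f"data row {row}: spot counts exceed n_total_placed"
            )
    return df


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    return _validate(df, schema_name)


def write_table(table: pd.DataFrame, path: str | Path, schema_name: str | None = None) -> Path:
    """Write a table as CSV (validating first when a schema is given)."""
    if schema_name is not None:
        table = _validate(table, schema_name)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config file into a plain mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping at top level")
    return data


def config_from_mapping(cls: type, data: Mapping[str, Any], **overrides: Any):
    """Build a config dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {unknown}")
    merged = {**data, **overrides}
    return cls(**merged)


def write_metadata(out_path: str | Path, command: str, config: Mapping[str, Any],
                   seed: int | None) -> Path:
    """Record the fully resolved run parameters next to an output file.

    The sidecar ``<out>.meta.json`` (command, resolved config, seed,
    package version) suffices to regenerate the output bit-identically for
    deterministic commands.
    """
    from . import __version__

    def _default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    meta = {
        "command": command,
        "config": dict(config),
        "seed": seed,
        "version": __version__,
    }
    meta_path = Path(str(out_path) + ".meta.json")
    meta_path.parent.mkdir(parents=True, exist_ok=True)
    meta_path.write_text(json.dumps(meta, indent=2, default=_default, sort_keys=True) + "\n")
    return meta_path
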