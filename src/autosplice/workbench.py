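"""Configuration, seed management and schema-validated table I/O.

All interchange is UTF-8 CSV with headers ('.' decimal); model parameters
and fit configuration round-trip through flat YAML/JSON key-value files.
Every CLI run writes a JSON manifest (config echo, seed, package version,
timestamp) next to its outputs so any artifact can be regenerated exactly.

A single global seed fans out to named per-stage substreams derived with
``numpy.random.SeedSequence`` over a stable hash of the stage label, so
adding a pipeline stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import ModelParameters, Trajectory, STATE_COLUMNS

__all__ = [
    "SchemaError",
    "substream_seed",
    "load_params",
    "save_params",
    "load_fit_spec",
    "save_fit_spec",
    "read_table",
    "write_table",
    "read_traces",
    "read_trajectory",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# --------------------------------------------------------------------------
# seeds
# --------------------------------------------------------------------------

def substream_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from the global seed and a label."""
    h = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed) % (2 ** 31), h])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# parameter configs
# --------------------------------------------------------------------------

def save_params(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_params(path: str | Path) -> ModelParameters:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: expected a flat key-value mapping")
    return ModelParameters.from_dict(d)


def save_fit_spec(spec, path: str | Path) -> None:
    path = Path(path)
    d = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_fit_spec(path: str | Path):
    from .inference import FitSpec

    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict) or "priors" not in d:
        raise SchemaError(f"{path}: expected a fit-spec mapping with priors")
    return FitSpec.from_dict(d)


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

SCHEMAS: dict[str, tuple[str, ...]] = {
    "traces": ("cell_id", "time_h", "intensity"),
    "truth": ("cell_id", "alpha_ec", "t_delay"),
    "features": ("cell_id", "I0", "If", "t0", "r", "sse", "flag"),
    "trajectory": ("time_h",) + STATE_COLUMNS + ("observable",),
    "records": ("gene", "binding_site_records"),
    "sweep": (),   # free-form: first column is the swept variable
    "curves": ("time_h",),
    "draws": ("chain", "iteration"),
}

_NUMERIC = {
    "traces": ("time_h", "intensity"),
    "truth": ("alpha_ec", "t_delay"),
    "features": ("I0", "If", "t0", "r", "sse"),
    "trajectory": ("time_h",) + STATE_COLUMNS + ("observable",),
    "records": ("binding_site_records",),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a named schema.

    Raises :class:`SchemaError` naming the missing column or the offending
    row for non-numeric cells.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    required = SCHEMAS[schema]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in _NUMERIC.get(schema, ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    if schema is not None and schema in SCHEMAS:
        for col in SCHEMAS[schema]:
            if col not in df.columns:
                raise SchemaError(f"cannot write {schema!r}: missing column {col!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_traces(path: str | Path) -> pd.DataFrame:
    return read_table(path, "traces")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return read_table(path, "trajectory")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    write_table(traj.to_frame(), path, "trajectory")


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir: str | Path, subcommand: str, config: dict,
                   seed: int, outputs: list[str]) -> Path:
    """Write a JSON provenance manifest next to a run's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    path = out_dir / f"manifest_{subcommand}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
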