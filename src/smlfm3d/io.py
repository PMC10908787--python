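"""Table and configuration I/O.

Localization tables are CSV with a header row and nanometre units in the
column names (ThunderSTORM-style naming where applicable); configs are
YAML; run manifests are JSON.  Round-trips are lossless and unknown
columns are preserved.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fit2d import LOC2D_COLUMNS, LOC3D_COLUMNS

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_localizations",
    "write_localizations",
    "read_deposited_table",
    "RunManifest",
    "load_yaml_config",
]

TRACK_COLUMNS = ["track_id", "frame", "x_nm", "y_nm", "z_nm"]

SCHEMAS = {
    "2d": LOC2D_COLUMNS,
    "3d": LOC3D_COLUMNS,
    "track": TRACK_COLUMNS,
}


class SchemaError(ValueError):
    """A table is missing mandatory columns for its declared schema."""


def _check_schema(df: pd.DataFrame, kind: str) -> None:
    try:
        required = SCHEMAS[kind]
    except KeyError:
        raise SchemaError(f"unknown schema {kind!r}; expected one of {sorted(SCHEMAS)}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table does not satisfy the {kind!r} schema; missing columns: "
            + ", ".join(missing)
        )


def read_localizations(path, kind: str) -> pd.DataFrame:
    """Read a localization CSV and validate it against a schema
    ('2d', '3d' or 'track').  Unknown columns are kept."""
    df = pd.read_csv(path)
    _check_schema(df, kind)
    return df


def write_localizations(df: pd.DataFrame, path, kind: str | None = None) -> None:
    if kind is not None:
        _check_schema(df, kind)
    out = df.drop(columns=[c for c in ("members",) if c in df.columns])
    out.to_csv(path, index=False)


#: Column mapping for per-view tables in the layout used by externally
#: deposited light-field localization datasets (MATLAB-exported CSV).
DEPOSITED_COLUMN_MAP = {
    "Frame": "frame",
    "View": "view",
    "X (nm)": "x_nm",
    "Y (nm)": "y_nm",
    "Sigma X (nm)": "sigma_x",
    "Sigma Y (nm)": "sigma_y",
    "Photons": "photons",
    "Background": "background",
    "Precision (nm)": "precision_nm",
}


def read_deposited_table(path) -> pd.DataFrame:
    """Best-effort reader for deposited per-view localization tables.

    Maps the documented external column names onto the internal 2D schema
    (case-insensitive; missing optional columns are filled with defaults).
    """
    df = pd.read_csv(path)
    lower_map = {k.lower(): v for k, v in DEPOSITED_COLUMN_MAP.items()}
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in lower_map:
            renames[col] = lower_map[key]
    df = df.rename(columns=renames)
    for col, default in (
        ("view", 0), ("sigma_x", np.nan), ("sigma_y", np.nan),
        ("photons", np.nan), ("background", 0.0), ("precision_nm", np.nan),
    ):
        if col not in df.columns:
            df[col] = default
    _check_schema(df, "2d")
    return df[LOC2D_COLUMNS + [c for c in df.columns if c not in LOC2D_COLUMNS]]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    seeds: dict
    software_version: str
    stage_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def save(self, path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest references missing output {out}")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(**blob)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_yaml_config(path) -> dict:
    import yaml

    with open(path) as fh:
        blob = yaml.safe_load(fh)
    if blob is None:
        return {}
    if not isinstance(blob, dict):
        raise SchemaError("config YAML must contain a mapping")
    return blob
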