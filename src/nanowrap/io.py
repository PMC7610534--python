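"""Schema-validated CSV readers/writers and flat key=value configuration.

All tabular data use one dialect: plain CSV with unit-bearing column names
(time_s, power_uW, wavelength_nm, ...).  Schemas declare the required columns
and, where an axis must be ordered (time, wavelength, delay), its
monotonicity; violations raise errors that name the offending column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableSchema",
    "SchemaError",
    "THERMOGRAM_SCHEMA",
    "HEATS_SCHEMA",
    "SPECTRUM_SCHEMA",
    "CORRELOGRAM_SCHEMA",
    "PLATE_SCHEMA",
    "read_table",
    "write_table",
    "read_config",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Required columns of a CSV table, with an optional strictly-increasing axis."""

    name: str
    columns: tuple[str, ...]
    monotone_column: str | None = None


THERMOGRAM_SCHEMA = TableSchema("thermogram", ("time_s", "power_uW"), "time_s")
HEATS_SCHEMA = TableSchema("heats", ("injection_index", "heat_uJ"))
SPECTRUM_SCHEMA = TableSchema("spectrum", ("wavelength_nm", "intensity"), "wavelength_nm")
CORRELOGRAM_SCHEMA = TableSchema("correlogram", ("delay_us", "g2"), "delay_us")
PLATE_SCHEMA = TableSchema("plate", ("well", "F_sample", "F_control", "F_max"))


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV table against a schema.

    Raises SchemaError naming any missing column or a non-monotone axis.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in schema.columns:
        if col not in df.columns:
            raise SchemaError(
                f"{schema.name} table {path} is missing column '{col}' "
                f"(found: {', '.join(df.columns)})"
            )
    if schema.monotone_column is not None:
        axis = df[schema.monotone_column].to_numpy(dtype=float)
        if not np.all(np.diff(axis) > 0):
            raise SchemaError(
                f"{schema.name} table {path}: column "
                f"'{schema.monotone_column}' must be strictly increasing"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV table; the inverse of read_table up to float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value configuration file ('#' starts a comment)."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ValueError(f"{path}:{lineno}: empty key")
        config[key] = value
    return config
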