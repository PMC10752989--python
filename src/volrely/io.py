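"""Readers and writers for the canonical volume table and reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .tables import COLUMNS, validate_volume_table

__all__ = ["read_volume_table", "write_volume_table", "load_config", "write_json_report"]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_volume_table(path, *, require_positive: bool = True) -> pd.DataFrame:
    """Read and validate a canonical volume CSV/TSV.

    The header must be exactly ``subject_id,method,roi,session,time_months,
    volume``; the delimiter is inferred from the extension. Duplicate keys,
    malformed numerics and (by default) non-positive volumes are rejected
    with row-numbered messages.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False, na_values=[""])
    if list(df.columns) != COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(COLUMNS)}, got {','.join(df.columns)}"
        )
    try:
        return validate_volume_table(df, require_positive=require_positive)
    except ValueError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_volume_table(table: pd.DataFrame, path) -> None:
    """Write a volume table in the canonical column order."""
    path = Path(path)
    table[COLUMNS].to_csv(path, sep=_sep(path), index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def write_json_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
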