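"""Tabular I/O with JSON sidecar schemas.

Tables travel as TSV with a ``<name>.schema.json`` sidecar recording column
names, dtypes and units.  Reading validates the table against its sidecar
and reports *all* violations at once.  TIV is canonically stored in litres
(column ``tiv_l``); a millilitre encoding (``tiv_ml`` or a unit tag in the
sidecar) is detected and converted on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "write_table", "read_table", "config_hash"]


class SchemaError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("schema violations:\n- " + "\n- ".join(violations))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schema.json")


_DTYPE_KINDS = {"i": "integer", "u": "integer", "f": "float", "b": "bool",
                "O": "string"}


def write_table(df: pd.DataFrame, path: str | Path,
                units: dict[str, str] | None = None,
                description: str = "") -> Path:
    """Write a TSV plus its JSON schema sidecar; returns the table path."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    schema = {
        "description": description,
        "n_rows": int(len(df)),
        "columns": [
            {
                "name": c,
                "dtype": _DTYPE_KINDS.get(df[c].dtype.kind, "string"),
                "unit": (units or {}).get(c, ""),
            }
            for c in df.columns
        ],
    }
    _sidecar(path).write_text(json.dumps(schema, indent=1))
    return path


def read_table(path: str | Path,
               require_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV, validate against its sidecar, normalise TIV to litres.

    Collects every violation (missing columns, dtype mismatches, row-count
    drift) before raising a single :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    violations: list[str] = []
    units: dict[str, str] = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        declared = {c["name"]: c for c in schema.get("columns", [])}
        units = {c["name"]: c.get("unit", "") for c in schema.get("columns", [])}
        for name, col in declared.items():
            if name not in df.columns:
                violations.append(f"declared column {name!r} missing from table")
                continue
            kind = _DTYPE_KINDS.get(df[name].dtype.kind, "string")
            want = col.get("dtype", kind)
            if want in ("integer", "float") and kind not in ("integer", "float"):
                violations.append(
                    f"column {name!r}: expected {want}, found {kind}")
        extra = [c for c in df.columns if c not in declared]
        if declared and extra:
            violations.append(f"undeclared columns present: {extra}")
        n = schema.get("n_rows")
        if n is not None and n != len(df):
            violations.append(f"row count {len(df)} != declared {n}")
    for c in require_columns or []:
        if c not in df.columns:
            violations.append(f"required column {c!r} missing")
    if violations:
        raise SchemaError(violations)

    # TIV unit reconciliation -> litres
    if "tiv_ml" in df.columns and "tiv_l" not in df.columns:
        df = df.rename(columns={"tiv_ml": "tiv_l"})
        df["tiv_l"] = df["tiv_l"] / 1000.0
    elif "tiv_l" in df.columns and units.get("tiv_l", "").lower() in ("ml", "milliliter", "millilitre"):
        df["tiv_l"] = df["tiv_l"] / 1000.0
    return df


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_hash(config) -> str:
    """Stable SHA-256 of a (nested) config dataclass/dict, for provenance."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
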