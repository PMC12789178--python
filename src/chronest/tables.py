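"""Schema-checked CSV table I/O.

All pipeline tables are UTF-8 comma-separated files with a header row.
Schemas map column names to ("int" | "float" | "str", required flag);
unknown columns warn, missing required columns raise, and type
violations raise with the offending row numbers (1-based, counting the
header as line 1).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableError", "read_table", "write_table", "SCHEMAS"]


class TableError(ValueError):
    pass


SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "onsets": {
        "female_id": ("str", True),
        "brood_id": ("str", True),
        "nest_box": ("str", True),
        "year": ("int", True),
        "date": ("int", True),
        "onset": ("float", True),
        "breeding_day": ("int", True),
        "stage": ("str", False),
    },
    "std_onsets": {
        "female_id": ("str", True),
        "brood_id": ("str", True),
        "nest_box": ("str", True),
        "year": ("int", True),
        "date": ("int", True),
        "onset": ("float", True),
        "breeding_day": ("int", True),
        "stage": ("str", False),
        "z": ("float", True),
        "date_n": ("int", True),
        "date_mean": ("float", True),
        "date_sd": ("float", True),
    },
    "broods": {
        "brood_id": ("str", True),
        "female_id": ("str", True),
        "year": ("int", True),
        "nest_box": ("str", True),
        "lay_date": ("int", True),
        "clutch_size": ("int", True),
        "incubation_start": ("int", True),
        "hatch_date": ("int", False),
        "max_observed_nestlings": ("int", True),
        "unhatched_eggs": ("int", True),
        "n_fledglings": ("int", True),
        "fledge_success": ("int", True),
        "second_brood": ("int", True),
        "deserted_flag": ("int", False),
        "failed_prehatch_flag": ("int", False),
    },
    "chronotypes": {
        "female_id": ("str", True),
        "chronotype": ("float", True),
        "n_onsets": ("int", True),
        "year": ("int", True),
        "brood_id": ("str", True),
    },
    "condition": {
        "female_id": ("str", True),
        "year": ("int", True),
        "weight": ("float", True),
        "tarsus": ("float", True),
        "time_of_day": ("float", True),
    },
    "nestlings": {
        "brood_id": ("str", True),
        "female_id": ("str", False),
        "year": ("int", False),
        "chick_age": ("int", True),
        "weight": ("float", True),
        "tarsus": ("float", True),
        "p3": ("float", True),
        "time_of_day": ("float", True),
    },
}


def read_table(path: str | Path, schema: "dict | str") -> pd.DataFrame:
    """Read and validate a CSV table against a schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c, (_, req) in schema.items() if req and c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    out = {}
    for col, (kind, req) in schema.items():
        if col not in df.columns:
            continue
        raw = df[col]
        if kind == "str":
            out[col] = raw
            continue
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()[:5]
            raise TableError(f"{path}: column {col!r} has non-numeric values at lines {rows}")
        if req and vals.isna().any():
            rows = (np.nonzero(vals.isna().to_numpy())[0] + 2).tolist()[:5]
            raise TableError(f"{path}: column {col!r} has missing values at lines {rows}")
        if kind == "int":
            nn = vals.dropna()
            if not np.allclose(nn, np.round(nn)):
                raise TableError(f"{path}: column {col!r} must be integer-valued")
            out[col] = vals.astype("Int64") if vals.isna().any() else vals.astype(int)
        else:
            out[col] = vals.astype(float)
    res = pd.DataFrame(out)
    return res[[c for c in df.columns if c in res.columns]]


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", float_format=float_format)
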