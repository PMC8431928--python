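"""CSV/JSON round-trips for cohort and centre tables (missing = empty cell)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CENTRE_COLUMNS, COHORT_COLUMNS

_COHORT_DTYPES = {
    "centre_id": "string", "age": float, "sex": "Int64", "charlson": "Int64",
    "pre_mrs": float, "pre_cpc": float, "rrs_reported": "Int64",
    "time_to_als": float, "witnessed": "Int64", "weekend": "Int64",
    "shift": "string", "shockable": "Int64", "location": "string",
    "mortality": "Int64", "cpc_discharge": float,
}


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={k: v for k, v in _COHORT_DTYPES.items()})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")
    # integer-like columns back to plain ints where fully observed
    for col, dt in _COHORT_DTYPES.items():
        if dt == "Int64" and not df[col].isna().any():
            df[col] = df[col].astype(int)
        elif dt == "string":
            df[col] = df[col].astype(object)
    return df


def write_centres(centres: pd.DataFrame, path: str | Path) -> None:
    centres.to_csv(path, index=False)


def read_centres(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"centre_id": "string"})
    missing = [c for c in CENTRE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"centre file lacks columns: {missing}")
    df["centre_id"] = df["centre_id"].astype(object)
    return df


def _sanitize(obj):
    """Make a report JSON-serialisable with stable float formatting."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not np.isfinite(v):
            return None
        return float(f"{v:.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_sanitize(obj), indent=2, sort_keys=True) + "\n"
    )
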