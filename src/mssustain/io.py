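"""Reading, validating and writing cohort tables and reports.

Cohort tables are long-format CSV (UTF-8, header row, one row per visit,
missing values empty).  Validation enforces the clinical contracts: EDSS
on the half-point lattice in [0, 10], non-decreasing visit times within
subject, and the presence of the key columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_cohort", "write_cohort",
           "validate_cohort", "write_report"]

REQUIRED_COLUMNS = ("subject_id", "dataset_id", "visit_time", "age", "sex",
                    "tiv")


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise ValueError naming the offending rows for contract violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if "edss" in df.columns:
        e = pd.to_numeric(df["edss"], errors="coerce")
        bad = df.index[
            e.notna()
            & ((e < 0) | (e > 10) | ((e * 2) - (e * 2).round()).abs().gt(1e-9))
        ]
        if len(bad):
            raise ValueError(
                f"EDSS off the 0.5 lattice in [0,10] at rows {list(bad[:10])}")
    offenders = []
    for sid, sub in df.groupby("subject_id", sort=False):
        t = sub["visit_time"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            offenders.append(sid)
    if offenders:
        raise ValueError(
            f"visit_time decreases within subjects: {offenders[:10]}")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} has no parseable rows") from exc
    if df.empty:
        raise ValueError(f"{path} contains a header but no rows")
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV that round-trips exactly (repr-precision floats)."""
    df.to_csv(path, index=False, float_format="%.17g")


def write_report(report: dict, path) -> None:
    """JSON report writer (numpy types coerced to plain Python)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="split"))
        raise TypeError(f"unserializable object of type {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=default)
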