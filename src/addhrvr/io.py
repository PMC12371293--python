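"""Plain-text input/output: the CSV schemas and the YAML run configuration.

Missing values are written as empty fields.  All tables are ordinary pandas
round-trips; the helpers here only pin column order and dtypes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hrv import IbiSeries

__all__ = [
    "read_ibi_csv",
    "write_ibi_csv",
    "read_minutes_csv",
    "write_csv",
    "load_config",
]

_MINUTE_COLS = ["person_id", "day", "minute_start", "rmssd", "sdnn", "hf", "lf",
                "met", "valid", "n_beats"]


def read_ibi_csv(path: str | Path) -> list[IbiSeries]:
    """Read an IBI stream table (person_id, day, t_seconds, ibi_ms) into series."""
    df = pd.read_csv(path)
    required = {"person_id", "day", "t_seconds", "ibi_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IBI csv is missing columns: {sorted(missing)}")
    out = []
    for (pid, day), g in df.groupby(["person_id", "day"], sort=True):
        g = g.sort_values("t_seconds")
        out.append(
            IbiSeries(
                person_id=str(pid),
                day=int(day),
                t=g["t_seconds"].to_numpy(dtype=float),
                ibi=g["ibi_ms"].to_numpy(dtype=float),
            )
        )
    return out


def write_ibi_csv(series: list[IbiSeries], path: str | Path) -> None:
    parts = [
        pd.DataFrame(
            {"person_id": s.person_id, "day": s.day, "t_seconds": s.t, "ibi_ms": s.ibi}
        )
        for s in series
    ]
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["person_id", "day", "t_seconds", "ibi_ms"]
    )
    df.to_csv(path, index=False)


def read_minutes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_MINUTE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"minute csv is missing columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write with missing values as empty fields and no index column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
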