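"""Plain-text I/O: CSV/TSV series ingest, curve and boundary export.

All positions written to or read from disk are 0-based sample indices into
the input file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mp_core import TimeSeries
from .regimes import RegimeBoundaries
from .segmentation import CorrectedArcCurve

__all__ = [
    "read_series",
    "write_series",
    "read_truth",
    "write_truth",
    "write_cac_tsv",
    "write_boundaries_json",
    "write_boundaries_tsv",
    "resample_to_length",
]


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                break
        else:
            raise ValueError(f"{path}: no data lines")
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    if ";" in line:
        return ";"
    return r"\s+"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    # cells stay strings: conversion happens later through numpy's correctly
    # rounded parser (pandas' default float parser is not round-trip exact)
    df = pd.read_csv(path, sep=sep, engine="python", header=None, comment="#", dtype=str)
    # header detection: a first row with any non-numeric cell is column names
    first = df.iloc[0]
    numeric_first = pd.to_numeric(first, errors="coerce")
    if numeric_first.isna().any():
        df.columns = [str(v) for v in first]
        df = df.iloc[1:].reset_index(drop=True)
    else:
        df.columns = [str(c) for c in df.columns]
    return df


def read_series(
    path, columns: Optional[Sequence] = None, sampling_rate_hz: Optional[float] = None
) -> list[TimeSeries]:
    """Read one channel per selected column from a CSV/TSV/plain-text file.

    ``columns`` may contain header names or 0-based column indices; by
    default every column is read.  Non-numeric cells and NaN rows are
    rejected with the offending line numbers in the error message.
    """
    df = _read_table(path)
    if columns is not None:
        cols = []
        for c in columns:
            if isinstance(c, int) or (isinstance(c, str) and c.isdigit() and c not in df.columns):
                idx = int(c)
                if idx >= df.shape[1]:
                    raise ValueError(f"column index {idx} out of range ({df.shape[1]} columns)")
                cols.append(df.columns[idx])
            else:
                if c not in df.columns:
                    raise ValueError(f"column {c!r} not found; available: {list(df.columns)}")
                cols.append(c)
        df = df[cols]
    out = []
    for name in df.columns:
        check = pd.to_numeric(df[name], errors="coerce")
        bad = np.flatnonzero(check.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"column {name!r}: non-numeric or missing values at data rows "
                f"{bad[:10].tolist()}" + ("..." if bad.size > 10 else "")
            )
        values = df[name].to_numpy(dtype=np.float64)  # exact round-trip parse
        out.append(TimeSeries(values, sampling_rate_hz=sampling_rate_hz))
    return out


def write_series(path, channels: Sequence["TimeSeries | np.ndarray"], delimiter: str = ",") -> None:
    arrays = [np.asarray(ch, dtype=np.float64) for ch in channels]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all channels must have equal length")
    np.savetxt(path, np.column_stack(arrays), delimiter=delimiter, fmt="%.17g")


def read_truth(path) -> np.ndarray:
    """Ground-truth boundary file: one integer sample index per line."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(int(float(line)))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: not an integer: {line!r}") from exc
    return np.asarray(values, dtype=np.int64)


def write_truth(path, positions: Sequence[int]) -> None:
    with open(path, "w") as fh:
        for p in positions:
            fh.write(f"{int(p)}\n")


def write_cac_tsv(path, cac: CorrectedArcCurve) -> None:
    """Two-column TSV: position, corrected-arc-curve value."""
    with open(path, "w") as fh:
        fh.write("# position\tcac\n")
        for i, v in enumerate(cac.values):
            fh.write(f"{i}\t{v:.10f}\n")


def write_boundaries_json(path, boundaries: RegimeBoundaries, params: Optional[dict] = None) -> None:
    payload = {
        "positions": boundaries.positions.tolist(),
        "cac_values": (
            boundaries.cac_values.tolist() if boundaries.cac_values is not None else None
        ),
        "num_requested": boundaries.num_requested,
        "exhausted": boundaries.exhausted,
        "params": params or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_boundaries_tsv(path, boundaries: RegimeBoundaries) -> None:
    with open(path, "w") as fh:
        fh.write("# position\tcac\n")
        vals = boundaries.cac_values
        for k, p in enumerate(boundaries.positions):
            v = float(vals[k]) if vals is not None else float("nan")
            fh.write(f"{int(p)}\t{v:.10f}\n")


def resample_to_length(x: "TimeSeries | np.ndarray", new_len: int) -> np.ndarray:
    """Linear resampling onto ``new_len`` evenly spaced points (for aligning
    curves from channels recorded at different rates before fusion)."""
    arr = np.asarray(x, dtype=np.float64)
    if new_len < 2:
        raise ValueError("new_len must be at least 2")
    grid = np.linspace(0.0, arr.size - 1, new_len)
    return np.interp(grid, np.arange(arr.size), arr)
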