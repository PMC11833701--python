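"""Readers and writers for the package's tabular and image formats.

All genomic intervals are 0-based half-open; image arrays are (z, y, x).
Table readers validate their schema and report the offending row on
failure; write/read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .comap import CrossoverCall, DepthTable, Genotype, WindowCountTable
from .errors import InvalidInputError
from .interference import FocusSet, InterferenceFit

__all__ = [
    "read_focus_table",
    "write_focus_table",
    "read_count_table",
    "write_count_table",
    "read_depth_table",
    "write_depth_table",
    "read_trace_table",
    "write_trace_table",
    "write_calls_bed",
    "read_calls_bed",
    "write_fit_report",
    "read_fit_report",
]


def _read_tsv(path: str | Path, columns: dict[str, type], kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InvalidInputError(f"{kind} {path}: unreadable ({exc})") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{kind} {path}: missing columns {sorted(missing)}")
    for col, typ in columns.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, counting the header
                raise InvalidInputError(
                    f"{kind} {path}: malformed value in column {col!r}, line {row}"
                )
            if coerced.isna().any():
                row = int(coerced.isna().idxmax()) + 2
                raise InvalidInputError(
                    f"{kind} {path}: missing value in column {col!r}, line {row}"
                )
            df[col] = coerced.astype(typ)
    return df


def read_focus_table(path: str | Path) -> list[FocusSet]:
    """Read foci from TSV ``chromosome_id  length  position`` (one row per focus)."""
    df = _read_tsv(
        path, {"chromosome_id": str, "length": float, "position": float}, "focus table"
    )
    sets = []
    for (cid, length), sub in df.groupby(["chromosome_id", "length"], sort=False):
        sets.append(
            FocusSet(str(cid), float(length), tuple(sorted(sub["position"].tolist())))
        )
    return sets


def write_focus_table(foci: Sequence[FocusSet], path: str | Path) -> None:
    rows = [
        {"chromosome_id": fs.chromosome_id, "length": fs.length, "position": p}
        for fs in foci
        for p in fs.positions
    ]
    pd.DataFrame(rows, columns=["chromosome_id", "length", "position"]).to_csv(
        path, sep="\t", index=False
    )


def read_count_table(path: str | Path, window_size: int = 5000) -> WindowCountTable:
    """Read 5-kb strain-specific counts: ``chrom  start  bristol  hawaiian``."""
    df = _read_tsv(
        path,
        {"chrom": str, "start": int, "bristol": int, "hawaiian": int},
        "count table",
    )
    return WindowCountTable(df, window_size)


def write_count_table(table: WindowCountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_depth_table(path: str | Path, window_size: int = 50_000) -> DepthTable:
    """Read 50-kb depth windows: ``chrom  start  depth``."""
    df = _read_tsv(path, {"chrom": str, "start": int, "depth": float}, "depth table")
    return DepthTable(df, window_size)


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read trace control points: ``nucleus_id  trace_id  order  z  y  x``.

    Accepts CSV or TSV (by extension).  Rows are sorted by ``order`` within
    each trace.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"nucleus_id", "trace_id", "order", "z", "y", "x"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace table {path}: missing columns {sorted(missing)}")
    return df.sort_values(["nucleus_id", "trace_id", "order"]).reset_index(drop=True)


def write_trace_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def write_calls_bed(calls: Sequence[CrossoverCall], path: str | Path) -> None:
    """Write crossover calls as a BED-like table (0-based half-open)."""
    rows = [
        {
            "chrom": c.chromosome_id,
            "left": c.interval[0],
            "right": c.interval[1],
            "left_class": c.left_class.value,
            "right_class": c.right_class.value,
            "support_reads": c.support_reads,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "left", "right", "left_class", "right_class", "support_reads"],
    ).to_csv(path, sep="\t", index=False)


def read_calls_bed(path: str | Path) -> list[CrossoverCall]:
    df = _read_tsv(
        path,
        {
            "chrom": str,
            "left": int,
            "right": int,
            "left_class": str,
            "right_class": str,
            "support_reads": int,
        },
        "call table",
    )
    return [
        CrossoverCall(
            chromosome_id=str(r.chrom),
            interval=(int(r.left), int(r.right)),
            left_class=Genotype(r.left_class),
            right_class=Genotype(r.right_class),
            support_reads=int(r.support_reads),
            flank_lengths=(0, 0),
        )
        for r in df.itertuples()
    ]


def write_fit_report(fit: InterferenceFit, path: str | Path) -> None:
    payload = {
        "shape": fit.shape,
        "scale": fit.scale,
        "loglik": fit.loglik,
        "shape_se": fit.shape_se,
        "n": fit.n,
        "capped": fit.capped,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_report(path: str | Path) -> InterferenceFit:
    d = json.loads(Path(path).read_text())
    return InterferenceFit(**d)
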