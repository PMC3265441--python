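"""Reading and writing simulation traces and run summaries.

Traces are comma-delimited text with a self-describing header
(``t_s,x_mm,v_mm_s,a_mm_s2,Fm_mN,Ff_mN,Fd_mN,Ft_mN``), written with 17
significant digits so a write/read round trip reproduces every double
bit-exactly.  Run summaries are JSON and always embed the fully
resolved configuration for provenance.
"""

from __future__ import annotations

import json

import pandas as pd

__all__ = ["TRACE_COLUMNS", "write_trace", "read_trace", "write_summary",
           "TraceFormatError"]

TRACE_COLUMNS = ("t_s", "x_mm", "v_mm_s", "a_mm_s2",
                 "Fm_mN", "Ff_mN", "Fd_mN", "Ft_mN")


class TraceFormatError(ValueError):
    """A trace file did not parse (message carries the line number)."""


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a trace table (header-only if the trace is empty)."""
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing columns {missing}")
    trace[list(TRACE_COLUMNS)].to_csv(path, index=False,
                                      float_format="%.17g")


def read_trace(path) -> pd.DataFrame:
    """Read a trace file; malformed content raises with a line number."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TraceFormatError(f"malformed trace file {path}: {exc}") from exc
    if tuple(df.columns) != TRACE_COLUMNS:
        raise TraceFormatError(
            f"line 1: expected header {','.join(TRACE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}")
    for col in TRACE_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise TraceFormatError(
                f"line {bad.idxmax() + 2}: non-numeric value in column {col}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
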