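"""Labeled-matrix TSV I/O with '#'-prefixed metadata headers.

Matrices are written as tab-separated tables, row ids in the first column,
sample ids in the header row, preceded by ``# key: value`` metadata lines
(config echo, seed). Round trips are lossless to 10 significant digits.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd


class MatrixIOError(ValueError):
    """Malformed matrix file (ragged rows, duplicate ids, ...)."""


def write_matrix(df: pd.DataFrame, path: str, meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_matrix(path: str) -> tuple[pd.DataFrame, dict]:
    """Read a labeled TSV matrix; returns (frame, metadata dict)."""
    meta: dict = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=n_meta)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MatrixIOError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        # +2: header line plus 1-based numbering; +n_meta metadata lines
        line_no = n_meta + 2 + int((df.index == dup).argmax()) + 1
        raise MatrixIOError(f"{path}: duplicate row id {dup!r} near line {line_no}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixIOError(f"{path}: duplicate column id {dup!r} in header")
    return df, meta
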