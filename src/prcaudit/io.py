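"""Reading and writing score/label tables and result files.

Input is delimited text (TSV by default), one row per entity, with a score
column and a 0/1 label column. Row order is preserved exactly — some
emulated tool behaviours depend on it. Labels must be literal 0/1: "truthy"
strings are rejected because silently mis-parsed label polarity is a classic
source of wrong AUPRC values.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import ScoredLabels, validate_scored_labels
from .errors import EmptyInputError, PRCAuditError

__all__ = ["read_scored_labels", "write_scored_labels"]


class ColumnError(PRCAuditError):
    """Requested column missing from the input file."""


class ParseError(PRCAuditError):
    """A cell could not be parsed; the offending row is reported."""


def read_scored_labels(
    path: str | Path | _io.IOBase,
    score_col: str | int = "score",
    label_col: str | int = "label",
    delimiter: str = "\t",
) -> ScoredLabels:
    """Read one classifier's scores and labels from delimited text.

    Columns may be named (header row) or positional (integer indices, no
    header assumed). Lines starting with ``#`` are comments.
    """
    positional = isinstance(score_col, int) and isinstance(label_col, int)
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            header=None if positional else 0,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty input file: {path}") from None
    if frame.empty:
        raise EmptyInputError(f"no data rows in: {path}")
    for col in (score_col, label_col):
        if col not in frame.columns:
            raise ColumnError(f"column {col!r} not found; available: {list(frame.columns)}")
    raw_scores = frame[score_col]
    raw_labels = frame[label_col]

    scores = pd.to_numeric(raw_scores, errors="coerce")
    bad = scores.isna() & raw_scores.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"unparseable score {raw_scores.iloc[row]!r} at data row {row + 1}")

    labels = pd.to_numeric(raw_labels, errors="coerce")
    bad = labels.isna() | ~labels.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"label must be 0 or 1, got {raw_labels.iloc[row]!r} at data row {row + 1}"
        )
    return validate_scored_labels(scores.to_numpy(float), labels.to_numpy(np.int64))


def write_scored_labels(
    data: ScoredLabels,
    path: str | Path | _io.IOBase,
    delimiter: str = "\t",
    header_comment: str | None = None,
) -> None:
    """Write a (score, label) table; round-trips exactly via repr floats."""
    frame = pd.DataFrame({"score": data.scores, "label": data.labels})
    buf = _io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    frame.to_csv(buf, sep=delimiter, index=False, float_format=None)
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
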