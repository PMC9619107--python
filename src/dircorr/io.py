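"""Delimited-text input/output and the bundled worked dataset."""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .types import PairedSeries

__all__ = [
    "load_worked_example",
    "read_response_matrix",
    "write_response_matrix",
    "pair_from_frame",
]


def load_worked_example() -> pd.DataFrame:
    """The bundled 20-person, 6-item worked dataset.

    Three binary items (A1-A3), three polytomous items (B1-B3) and the
    score X, constructed so that A1/B1 follow a deterministic item-score
    pattern, A2/B2 add minor response error, and A3/B3 add ties and
    crossing pairs.  Indexed by test taker; columns A1..B3 and X.
    """
    with resources.files("dircorr.data").joinpath("worked_example.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame.set_index("person")


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_response_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited person x item matrix with a header row.

    Every cell must be numeric and present; a missing or non-numeric cell
    raises :class:`InvalidInputError` naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise InvalidInputError(f"empty file: {path}")
    delim = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim)
    if frame.empty or frame.shape[1] == 0:
        raise InvalidInputError(f"no data rows in {path}")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna()]
        if len(bad):
            raise InvalidInputError(
                f"non-numeric or missing cell at row {bad[0] + 2}, "
                f"column {col!r} in {path}"
            )
        frame[col] = numeric
    return frame


def write_response_matrix(frame: pd.DataFrame, path: str | Path,
                          delimiter: str = ",") -> None:
    """Write a matrix as delimited text (round-trips with the reader)."""
    pd.DataFrame(frame).to_csv(path, sep=delimiter, index=False)


def pair_from_frame(
    frame: pd.DataFrame, item: str | int, score: str | int
) -> PairedSeries:
    """Build a :class:`PairedSeries` from two columns selected by name or
    0-based position."""

    def _col(sel: str | int) -> np.ndarray:
        if isinstance(sel, int):
            if not 0 <= sel < frame.shape[1]:
                raise InvalidInputError(f"column index {sel} out of range")
            return frame.iloc[:, sel].to_numpy()
        if sel not in frame.columns:
            raise InvalidInputError(f"no column named {sel!r}")
        return frame[sel].to_numpy()

    return PairedSeries(_col(item), _col(score))
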