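"""Table reading and weight serialization for the command-line surface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from greedystack.errors import InputError
from greedystack.greedy import WeightVector

__all__ = ["read_table", "write_weights", "read_weights"]


def read_table(path: str | Path, delimiter: str = "auto") -> pd.DataFrame:
    """Read a headered CSV/TSV of numeric columns into a DataFrame.

    ``delimiter`` is ``auto`` (sniffed from the extension, ``.tsv``/``.txt``
    meaning tab), ``comma`` or ``tab``. Missing values are a hard error
    reported with their (row, column) coordinates — the weighting
    algorithms assume a complete matrix and imputation is out of scope.
    Non-numeric cells are an error naming the offending column.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    if delimiter == "auto":
        sep = "\t" if p.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    elif delimiter == "comma":
        sep = ","
    elif delimiter == "tab":
        sep = "\t"
    else:
        raise InputError(f"delimiter must be auto|comma|tab, got {delimiter!r}")
    try:
        df = pd.read_csv(p, sep=sep)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty file: {p}") from None
    if df.shape[0] == 0:
        raise InputError(f"no data rows in {p}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise InputError(f"duplicate column names in {p}: {dupes}")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        coords = [(int(r), df.columns[c]) for r, c in zip(rows[:10], cols[:10])]
        raise InputError(f"missing values in {p} at (row, column): {coords}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise InputError(f"non-numeric values in column {col!r} of {p}")
    return df


def write_weights(w: WeightVector, meta: dict, path: str | Path) -> None:
    """Serialize weights plus run metadata as JSON; round-trips exactly.

    Weights are written at full float precision; a ``percentages`` view is
    added for readability since simplex weights read directly as
    percentage shares.
    """
    payload = {
        "weights": [float(x) for x in w.w],
        "percentages": w.as_percentages(),
        "provenance": w.provenance,
        **meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_weights(path: str | Path) -> tuple[WeightVector, dict]:
    """Load a weight JSON written by :func:`write_weights`."""
    payload = json.loads(Path(path).read_text())
    w = WeightVector(
        np.array(payload["weights"], dtype=float),
        provenance=payload.get("provenance", "unspecified"),
    )
    meta = {k: v for k, v in payload.items() if k not in ("weights", "percentages", "provenance")}
    return w, meta
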