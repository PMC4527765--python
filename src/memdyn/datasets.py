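"""Locating the experimental observation table.

The published observation table (6419 cell observations, 150 features,
122 cells over 19 experiments) is distributed as a supplementary
spreadsheet alongside the article and is not bundled here. To run the
data-based analyses, place it under ``data/`` in the repository root (or
pass an explicit path), either as

* ``data/s1/``: a CSV triplet ``features.csv``, ``processes.csv``,
  ``index.csv`` exported from the three sheets, or
* ``data/s1_dataset.xlsx``: the workbook converted to XLSX with sheets
  named ``features``, ``processes`` and ``index``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ingest import read_dataset

__all__ = ["locate_experimental_dataset", "load_experimental_dataset"]

_SEARCH = (
    ("s1", "csv-triplet"),
    ("s1_dataset.xlsx", "s1-spreadsheet"),
    ("S1_Dataset.xlsx", "s1-spreadsheet"),
)


def locate_experimental_dataset(root: str | Path = "data") -> tuple[Path, str] | None:
    """Return (path, dialect) of the experimental table, or None if absent."""
    root = Path(root)
    for name, dialect in _SEARCH:
        p = root / name
        if p.exists():
            return p, dialect
    return None


def load_experimental_dataset(root: str | Path = "data") -> pd.DataFrame:
    """Load the experimental observation table, raising if it is missing."""
    found = locate_experimental_dataset(root)
    if found is None:
        raise FileNotFoundError(
            "experimental observation table not found: place the published "
            "supplementary table under data/s1/ (CSV triplet) or as "
            "data/s1_dataset.xlsx — see memdyn.datasets docstring"
        )
    path, dialect = found
    return read_dataset(path, dialect)
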