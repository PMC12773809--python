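"""Delimited-matrix and label I/O.

Matrices travel as TSV with the first column holding feature IDs and
the header row holding sample IDs (``features_as_rows=True``, the
default on disk) or transposed. Missing values are rejected: the
analysis is complete-case by contract.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import OmicsBlock


def read_matrix(path: str | Path, name: str | None = None, modality: str = "",
                features_as_rows: bool = True, sep: str = "\t") -> OmicsBlock:
    """Read one omics block; duplicate IDs and missing values are errors."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise ValueError(f"{path.name}: missing value at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r} (complete cases required)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicated ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path.name}: duplicated ID {dup!r}")
    if features_as_rows:
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = "feature_id"
    return OmicsBlock(name or path.stem, modality or (name or path.stem), df)


def write_matrix(block: OmicsBlock, path: str | Path,
                 features_as_rows: bool = True, sep: str = "\t") -> None:
    mat = block.data.T if features_as_rows else block.data
    mat.to_csv(path, sep=sep)


def read_labels(path: str | Path, sep: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, class) table."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expected a class column")
    s = df.iloc[:, 0]
    if s.isna().any():
        raise ValueError(f"{path}: missing class label")
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample ID {dup!r}")
    s.name = "class"
    return s
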