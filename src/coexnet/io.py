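"""Delimited-text readers and writers for expression and network matrices.

Expression matrices are stored genes-as-rows: the header row carries sample
identifiers, the first column gene identifiers. Square matrices (association
or adjacency) carry the same identifiers in both the header and first column.
Edge lists are three-column TSV (id_a, id_b, weight) over the upper triangle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._validation import ValidationError, as_expression_frame, as_square_frame

# Full float64 round trip: 17 significant digits.
_FLOAT_FMT = "%.17g"


def read_expression(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    Parameters
    ----------
    path : str or path-like
        File whose first row is a header of sample ids and whose first
        column holds gene ids.
    delimiter : str
        Field separator, tab by default ("," for CSV).

    Returns
    -------
    pandas.DataFrame
        Validated expression matrix (no duplicate ids, no missing cells,
        n >= 2 genes, m >= 3 samples).
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse expression file {path}: {exc}") from exc
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValidationError(
            f"non-numeric expression value in column {col!r} at gene {where!r}"
        )
    return as_expression_frame(df)


def write_expression(expr: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write an expression matrix in the layout `read_expression` expects."""
    df = as_expression_frame(expr)
    df.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)


def write_matrix(mat, path, delimiter: str = "\t", ids=None) -> None:
    """Write a square association/adjacency matrix as delimited text.

    Round-trips through `read_matrix` to within 1e-12 (17-digit floats).
    """
    df = as_square_frame(mat, ids=ids)
    if df.shape[0] < 2:
        raise ValidationError("square matrices must have n >= 2")
    df.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)


def read_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a square matrix written by `write_matrix`."""
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse matrix file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return as_square_frame(df)


def write_edge_list(mat, path, delimiter: str = "\t", threshold: float = 0.0) -> None:
    """Write the upper triangle of a square matrix as (id_a, id_b, weight) rows.

    Entries with |weight| <= threshold are dropped, which keeps sparse
    inference outputs compact.
    """
    df = as_square_frame(mat)
    ids = list(df.index)
    a = df.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = np.abs(a[iu, ju]) > threshold
    out = pd.DataFrame(
        {
            "id_a": [ids[i] for i in iu[keep]],
            "id_b": [ids[j] for j in ju[keep]],
            "weight": a[iu, ju][keep],
        }
    )
    out.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def write_labels(labels: pd.Series, path, delimiter: str = "\t") -> None:
    """Write per-gene module labels (id, module) with a header row."""
    s = pd.Series(labels).astype(int)
    s.index = s.index.astype(str)
    s.rename("module").to_csv(path, sep=delimiter, index_label="id")


def read_labels(path, delimiter: str = "\t") -> pd.Series:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if "module" not in df.columns:
        raise ValidationError("label file must have a 'module' column")
    s = df["module"].astype(int)
    s.index = s.index.astype(str)
    return s
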