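"""Shared validation helpers for expression and network matrices.

Conventions used throughout the package:

* an *expression matrix* is a pandas DataFrame with genes as rows
  (index = gene identifiers) and samples as columns;
* a *square matrix* (association or adjacency) is a pandas DataFrame whose
  index and columns both carry the gene identifiers, in the same order;
* scikit-learn estimators operate on plain arrays oriented samples x genes,
  the functional wrappers handle the transposition and labelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ADJ_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class DegenerateInputError(ValidationError):
    """Raised when an input is constant/degenerate for the requested measure."""


def as_expression_frame(expr) -> pd.DataFrame:
    """Validate and return a genes x samples expression DataFrame.

    Accepts a DataFrame (genes as rows) or a 2-d array (gene/sample labels
    generated as g1..gn / s1..sm). Requires n >= 2 genes, m >= 3 samples,
    unique identifiers and no missing values.
    """
    if isinstance(expr, pd.DataFrame):
        df = expr.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        arr = np.asarray(expr, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("expression data must be 2-dimensional")
        df = pd.DataFrame(
            arr,
            index=[f"g{i + 1}" for i in range(arr.shape[0])],
            columns=[f"s{j + 1}" for j in range(arr.shape[1])],
        )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifiers: {dups}")
    n, m = df.shape
    if n < 2:
        raise ValidationError(f"need at least 2 genes, got {n}")
    if m < 3:
        raise ValidationError(f"need at least 3 samples, got {m}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            "missing or non-finite expression value at gene "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return df.astype(float)


def check_no_constant_rows(df: pd.DataFrame) -> None:
    """Reject genes with zero variance (undefined for every pairwise measure)."""
    values = df.to_numpy()
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        genes = df.index[constant].tolist()
        raise DegenerateInputError(f"constant expression for genes: {genes}")


def as_square_frame(mat, ids=None) -> pd.DataFrame:
    """Coerce an n x n matrix (array or DataFrame) to a labelled DataFrame."""
    if isinstance(mat, pd.DataFrame):
        df = mat.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValidationError("square matrix must have identical row/column ids")
    else:
        arr = np.asarray(mat, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"expected a square matrix, got shape {arr.shape}")
        if ids is None:
            ids = [f"g{i + 1}" for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=list(ids), columns=list(ids))
    return df.astype(float)


def validate_adjacency(values, ids=None, tol: float = ADJ_TOL) -> pd.DataFrame:
    """Check the adjacency axioms and return the matrix with an exact unit diagonal.

    An adjacency matrix must be symmetric, have entries in [0, 1] and a unit
    diagonal, all within ``tol``. The returned copy has its diagonal set to
    exactly 1.
    """
    df = as_square_frame(values, ids=ids)
    a = df.to_numpy()
    lo, hi = a.min(), a.max()
    if lo < -tol or hi > 1 + tol:
        idx = np.unravel_index(np.argmax(np.abs(a - np.clip(a, 0, 1))), a.shape)
        raise ValidationError(
            f"adjacency range violation: entry ({df.index[idx[0]]}, "
            f"{df.columns[idx[1]]}) = {a[idx]!r} outside [0, 1]"
        )
    asym = np.abs(a - a.T)
    if asym.max() > tol:
        idx = np.unravel_index(np.argmax(asym), a.shape)
        raise ValidationError(
            f"adjacency symmetry violation: |A_ij - A_ji| = {asym[idx]!r} at "
            f"({df.index[idx[0]]}, {df.columns[idx[1]]})"
        )
    d = np.diag(a)
    if np.abs(d - 1).max() > tol:
        i = int(np.argmax(np.abs(d - 1)))
        raise ValidationError(
            f"adjacency diagonal violation: A_ii = {d[i]!r} at {df.index[i]}"
        )
    out = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def symmetric_part_ok(a: np.ndarray, tol: float = ADJ_TOL) -> bool:
    return bool(np.abs(a - a.T).max() <= tol)
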