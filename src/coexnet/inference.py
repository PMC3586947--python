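"""Mutual-information network inference: RELNET, CLR, MRNET and ARACNE.

All four algorithms post-process a symmetric pairwise MI matrix:

* RELNET keeps edges with MI >= tau and zeroes the rest.
* CLR standardizes each MI value against the empirical background of its
  two incident nodes, z_ij = sqrt(z_i^2 + z_j^2) with
  z_i = max(0, (MI_ij - mu_i) / sigma_i) over row i's off-diagonal values.
* MRNET runs maximum-relevance/minimum-redundancy forward selection with
  every node as target; a predictor entering the selection for target y is
  scored by its relevance MI(x, y) minus its mean redundancy with the
  already-selected set, and each pair keeps the better of its two
  directional scores (floored at 0).
* ARACNE applies the data-processing inequality: after removing edges with
  MI <= tau, an edge (i, j) is dropped whenever some third node k satisfies
  MI_ij <= min(MI_ik, MI_kj) - tolerance; all triplets are evaluated
  against the same input matrix and flagged edges are removed together.

The outputs are association matrices; ``inferred_to_adjacency`` rescales
them by the maximum off-diagonal entry into a valid adjacency.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import ValidationError, as_square_frame, symmetric_part_ok


def _check_mi(mi_mat, min_n: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    df = as_square_frame(mi_mat)
    a = df.to_numpy()
    if not symmetric_part_ok(a, tol=1e-9):
        raise ValidationError("MI matrix must be symmetric")
    if df.shape[0] < min_n:
        raise ValidationError(f"need at least {min_n} variables")
    return df, a.copy()


def relnet(mi_mat, tau: float = 0.0) -> pd.DataFrame:
    """Relevance network: zero out off-diagonal entries with MI < tau."""
    df, a = _check_mi(mi_mat)
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off & (a < tau)] = 0.0
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def clr(mi_mat) -> pd.DataFrame:
    """Context likelihood of relatedness scores from an MI matrix.

    Row statistics use the off-diagonal entries only (sample sd, ddof=1);
    a zero-variance row contributes z = 0 with a warning.  The output is
    symmetric with a zero diagonal.
    """
    df, a = _check_mi(mi_mat, min_n=3)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows = a[off].reshape(n, n - 1)
    mu = rows.mean(axis=1)
    sigma = rows.std(axis=1, ddof=1)
    degenerate = sigma == 0
    if degenerate.any():
        warnings.warn(
            f"CLR: zero MI variance for rows {df.index[degenerate].tolist()}; "
            "their z contributions are set to 0",
            stacklevel=2,
        )
        sigma = np.where(degenerate, 1.0, sigma)
    z = (a - mu[:, None]) / sigma[:, None]
    z = np.maximum(z, 0.0)
    z[degenerate, :] = 0.0
    out = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _mrmr_scores_for_target(a: np.ndarray, target: int) -> np.ndarray:
    """Forward-selection entry scores of all predictors for one target.

    The first predictor is the one with the highest MI with the target and
    scores that MI; thereafter the candidate maximizing
    relevance - mean redundancy over the selected set enters with that
    score, until all predictors are ordered.  Ties break on lowest index.
    """
    n = a.shape[0]
    candidates = [j for j in range(n) if j != target]
    scores = np.zeros(n)
    selected: list[int] = []
    redundancy_sum = np.zeros(n)
    while candidates:
        if not selected:
            vals = [a[j, target] for j in candidates]
        else:
            vals = [
                a[j, target] - redundancy_sum[j] / len(selected)
                for j in candidates
            ]
        best = int(np.argmax(vals))  # np.argmax returns the first (lowest) index
        j = candidates.pop(best)
        scores[j] = vals[best]
        selected.append(j)
        for k in candidates:
            redundancy_sum[k] += a[k, j]
    return scores


def mrnet(mi_mat) -> pd.DataFrame:
    """MRNET pair scores: max over the two directional MRMR entry scores.

    Negative final scores are floored at 0; the diagonal is 0.
    """
    df, a = _check_mi(mi_mat)
    n = a.shape[0]
    directional = np.vstack(
        [_mrmr_scores_for_target(a, t) for t in range(n)]
    )  # directional[t, j] = score of predictor j for target t
    out = np.maximum(directional, directional.T)
    out = np.maximum(out, 0.0)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def aracne(mi_mat, tau: float = 0.0, dpi_tolerance: float = 0.0) -> pd.DataFrame:
    """ARACNE: threshold at tau, then prune indirect edges with the DPI.

    All (i, j, k) triplets of surviving edges are checked against the same
    post-threshold matrix; edges flagged by
    MI_ij <= min(MI_ik, MI_kj) - dpi_tolerance are removed simultaneously.
    """
    if not 0.0 <= dpi_tolerance <= 1.0:
        raise ValidationError("dpi_tolerance must lie in [0, 1]")
    df, a = _check_mi(mi_mat)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    a[off & (a <= tau)] = 0.0
    present = (a > 0) & off
    remove = np.zeros_like(present)
    for i in range(n):
        for j in range(i + 1, n):
            if not present[i, j]:
                continue
            for k in range(n):
                if k == i or k == j:
                    continue
                if not (present[i, k] and present[k, j]):
                    continue
                if a[i, j] <= min(a[i, k], a[k, j]) - dpi_tolerance:
                    remove[i, j] = remove[j, i] = True
                    break
    a[remove] = 0.0
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def inferred_to_adjacency(S) -> pd.DataFrame:
    """Rescale a non-negative inference score matrix into an adjacency.

    Divides by the maximum off-diagonal score (bounded rescaling with lower
    bound 0 and power 1) and sets a unit diagonal.
    """
    df = as_square_frame(S)
    a = df.to_numpy().copy()
    if a.min() < 0:
        raise ValidationError("inference scores must be non-negative")
    off = ~np.eye(a.shape[0], dtype=bool)
    top = a[off].max() if a.shape[0] > 1 else 0.0
    if top == 0:
        raise ValidationError("all-zero score matrix cannot be rescaled")
    a = np.clip(a / top, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


class MINetworkInference(TransformerMixin, BaseEstimator):
    """Matrix-level transformer: MI matrix -> inference-score adjacency.

    Applies one of the four algorithms to a pairwise MI matrix (the
    diagonal is ignored) and rescales the scores into an adjacency.

    Parameters
    ----------
    method : {"relnet", "clr", "mrnet", "aracne"}
    tau : float
        Initial MI threshold for relnet/aracne.
    dpi_tolerance : float in [0, 1]
        ARACNE data-processing-inequality tolerance.
    """

    def __init__(self, method: str = "aracne", tau: float = 0.0,
                 dpi_tolerance: float = 0.0):
        self.method = method
        self.tau = tau
        self.dpi_tolerance = dpi_tolerance

    def _apply(self, mi_df: pd.DataFrame) -> pd.DataFrame:
        mi_df = mi_df.copy()
        # inference operates on pairwise scores; blank the entropy diagonal
        a = mi_df.to_numpy()
        np.fill_diagonal(a, 0.0)
        if self.method == "relnet":
            return relnet(a, tau=self.tau)
        if self.method == "clr":
            return clr(a)
        if self.method == "mrnet":
            return mrnet(a)
        if self.method == "aracne":
            return aracne(a, tau=self.tau, dpi_tolerance=self.dpi_tolerance)
        raise ValueError(f"unknown inference method {self.method!r}")

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        df = as_square_frame(X)
        scores = self._apply(df)
        return inferred_to_adjacency(scores).to_numpy()
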