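"""Association -> adjacency transforms and the topological overlap matrix.

A similarity matrix S with known element-wise bounds is rescaled into an
adjacency by

    A_ij = ((S_ij - lower_ij) / (upper_ij - lower_ij))^beta,

which specializes to the hard threshold A_ij = 1{s_ij >= tau}, the unsigned
soft threshold |cor|^beta (default beta 6) and the signed soft threshold
((1 + cor)/2)^beta (default beta 12).  The topological overlap transform
replaces direct connection strength by shared-neighbour overlap:

    TOM_ij = (sum_{l != i,j} A_il A_lj + A_ij)
             / (min(k_i, k_j) - A_ij + 1),     k_i = sum_{l != i} A_il,

which damps spurious isolated edges and strengthens edges embedded in a
common neighbourhood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import ValidationError, as_square_frame, validate_adjacency

DEFAULT_BETA_UNSIGNED = 6.0
DEFAULT_BETA_SIGNED = 12.0


def hard_threshold(sim, tau: float) -> pd.DataFrame:
    """Binary adjacency 1{s_ij >= tau} (inclusive) with unit diagonal."""
    df = as_square_frame(sim)
    s = df.to_numpy()
    if s.min() < 0 or s.max() > 1:
        raise ValidationError("hard threshold expects similarities in [0, 1]")
    a = (s >= tau).astype(float)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def soft_adjacency(cor_mat, mode: str = "unsigned", beta: float | None = None) -> pd.DataFrame:
    """Weighted adjacency |cor|^beta (unsigned) or ((1+cor)/2)^beta (signed)."""
    df = as_square_frame(cor_mat)
    c = df.to_numpy()
    if np.abs(c).max() > 1 + 1e-12:
        raise ValidationError("correlations must lie in [-1, 1]")
    c = np.clip(c, -1.0, 1.0)
    if mode == "unsigned":
        beta = DEFAULT_BETA_UNSIGNED if beta is None else float(beta)
        a = np.abs(c) ** beta
    elif mode == "signed":
        beta = DEFAULT_BETA_SIGNED if beta is None else float(beta)
        a = (0.5 + 0.5 * c) ** beta
    else:
        raise ValidationError(f"unknown soft-threshold mode {mode!r}")
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def rescale_adjacency(S, lower, upper, beta: float = 1.0) -> pd.DataFrame:
    """General bounded rescaling ((S - lower)/(upper - lower))^beta.

    ``lower`` and ``upper`` may be scalars or matrices; with lower=-1,
    upper=1 this reproduces the signed soft threshold exactly.
    """
    df = as_square_frame(S)
    s = df.to_numpy()
    lo = np.broadcast_to(np.asarray(lower, dtype=float), s.shape)
    hi = np.broadcast_to(np.asarray(upper, dtype=float), s.shape)
    if (hi <= lo).any():
        raise ValidationError("upper bound must exceed lower bound everywhere")
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    a = np.clip((s - lo) / (hi - lo), 0.0, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def tom(adj) -> pd.DataFrame:
    """Topological overlap transform of a valid adjacency matrix.

    Uses the matrix product for the shared-neighbour sum with the l in
    {i, j} contributions removed; equals the triple-loop definition to
    machine precision (asserted in the test suite).
    """
    df = validate_adjacency(adj)
    a = df.to_numpy()
    # sum_{l != i,j} A_il A_lj = (A @ A)_ij - A_ii A_ij - A_ij A_jj
    shared = a @ a - 2.0 * a  # A_ii = A_jj = 1
    k = a.sum(axis=1) - 1.0  # connectivity excluding the diagonal
    numer = shared + a
    denom = np.minimum(k[:, None], k[None, :]) - a + 1.0
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below; avoid 0/0
    t = numer / denom
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=df.index, columns=df.columns)


class SoftThreshold(TransformerMixin, BaseEstimator):
    """Matrix-level transformer: correlation matrix -> soft-threshold adjacency."""

    def __init__(self, mode: str = "unsigned", beta: float | None = None):
        self.mode = mode
        self.beta = beta

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return soft_adjacency(X, mode=self.mode, beta=self.beta).to_numpy()


class HardThreshold(TransformerMixin, BaseEstimator):
    """Matrix-level transformer: similarity in [0, 1] -> binary adjacency."""

    def __init__(self, tau: float = 0.5):
        self.tau = tau

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return hard_threshold(np.abs(np.asarray(X, dtype=float)), self.tau).to_numpy()


class TOM(TransformerMixin, BaseEstimator):
    """Matrix-level transformer applying the topological overlap transform."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return tom(X).to_numpy()
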