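"""Mutual-information based network adjacencies and the cor-MI map.

Three entropy-normalized MI adjacencies are implemented, all mapping a
pairwise MI matrix (diagonal = marginal entropies H_i) into [0, 1]:

* symmetric uncertainty      ASU_ij  = 2 MI_ij / (H_i + H_j)
* universal version 1        AUV1_ij = ASU_ij / (2 - ASU_ij)
* universal version 2        AUV2_ij = MI_ij / max(H_i, H_j)

1 - AUV1 and 1 - AUV2 are universal distance functions (they satisfy the
triangle inequality).  Under bivariate normality with sqrt(m) equal-width
bins, AUV2 is accurately approximated from the correlation alone by the
monotone "cor-MI" function

    F(s) = log(1 + eps - s^2) / log(eps) * (1 - omega) + omega,
    omega = 0.43 m^-0.30,  eps = omega^2.2,

which maps [0, 1] to [0, 1] whenever 0 < eps <= omega < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import (
    DegenerateInputError,
    ValidationError,
    as_square_frame,
    validate_adjacency,
)
from .information import MutualInformation

_VARIANTS = ("asu", "auv1", "auv2")


def _mi_and_entropies(mi_mat, entropies=None):
    df = as_square_frame(mi_mat)
    mi = df.to_numpy()
    if entropies is None:
        h = np.diag(mi).copy()
    else:
        h = np.asarray(
            entropies.to_numpy() if isinstance(entropies, pd.Series) else entropies,
            dtype=float,
        ).ravel()
    if h.size != mi.shape[0]:
        raise ValidationError("entropy vector length must match the MI matrix")
    if (h <= 0).any():
        bad = df.index[np.flatnonzero(h <= 0)].tolist()
        raise DegenerateInputError(f"zero entropy for genes: {bad}")
    return df, mi, h


def asu_adjacency(mi_mat, entropies=None) -> pd.DataFrame:
    """Symmetric-uncertainty adjacency 2 MI_ij / (H_i + H_j), clipped to [0, 1]."""
    df, mi, h = _mi_and_entropies(mi_mat, entropies)
    a = 2.0 * mi / (h[:, None] + h[None, :])
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def auv1_adjacency(asu) -> pd.DataFrame:
    """Universal version-1 adjacency ASU / (2 - ASU), a monotone map of ASU."""
    df = validate_adjacency(asu)
    a = df.to_numpy()
    out = a / (2.0 - a)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def auv2_adjacency(mi_mat, entropies=None) -> pd.DataFrame:
    """Universal version-2 adjacency MI_ij / max(H_i, H_j), clipped to [0, 1]."""
    df, mi, h = _mi_and_entropies(mi_mat, entropies)
    a = mi / np.maximum(h[:, None], h[None, :])
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


def universal_dissimilarity(adj) -> pd.DataFrame:
    """1 - A with a zero diagonal; a universal distance for AUV1/AUV2 input."""
    df = validate_adjacency(adj)
    d = 1.0 - df.to_numpy()
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.columns)


@dataclass
class CorMIParams:
    """Sample-size dependent parameters of the cor-MI function."""

    omega: float
    epsilon: float
    m: int


def cor_mi_params(m: int) -> CorMIParams:
    """omega = 0.43 m^-0.30 and eps = omega^2.2 for sample size m >= 4."""
    if m < 4:
        raise ValidationError("cor-MI parameters require m >= 4")
    omega = 0.43 * m ** (-0.30)
    epsilon = omega**2.2
    if not 0 < epsilon <= omega < 1:
        raise AssertionError(
            f"cor-MI parameter constraint violated: eps={epsilon}, omega={omega}"
        )
    return CorMIParams(omega=omega, epsilon=epsilon, m=m)


def f_cor_mi(s, params: CorMIParams):
    """The cor-MI map F(s) = log(1 + eps - s^2)/log(eps) * (1-omega) + omega.

    Strictly increasing on [0, 1] with F(1) = 1; accepts scalars or arrays.
    """
    s_arr = np.asarray(s, dtype=float)
    if (s_arr < 0).any() or (s_arr > 1).any():
        raise ValidationError("f_cor_mi is defined on s in [0, 1]")
    eps, omega = params.epsilon, params.omega
    val = np.log(1.0 + eps - s_arr**2) / np.log(eps) * (1.0 - omega) + omega
    val = np.clip(val, 0.0, 1.0)
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(val)
    return val


def predict_auv2_from_cor(cor_mat, m: int) -> pd.DataFrame:
    """Predict the AUV2 adjacency entry-wise as F(|cor_ij|) with unit diagonal."""
    df = as_square_frame(cor_mat)
    c = df.to_numpy()
    if (np.abs(c) > 1 + 1e-12).any():
        raise ValidationError("correlation entries must lie in [-1, 1]")
    params = cor_mi_params(m)
    a = f_cor_mi(np.clip(np.abs(c), 0.0, 1.0), params)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.columns)


class MIAdjacency(TransformerMixin, BaseEstimator):
    """Expression -> entropy-normalized MI adjacency, scikit-learn style.

    Combines equal-width discretization, entropy/MI estimation and one of
    the three normalizations in a single transformer mapping an (m, n)
    sample-by-gene array to an (n, n) adjacency.

    Parameters
    ----------
    variant : {"asu", "auv1", "auv2"}
    n_bins : int or "auto"
    estimator : {"plugin", "miller_madow"}
    """

    def __init__(self, variant: str = "auv2", n_bins="auto",
                 estimator: str = "miller_madow"):
        self.variant = variant
        self.n_bins = n_bins
        self.estimator = estimator

    def fit(self, X, y=None):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown MI adjacency variant {self.variant!r}")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown MI adjacency variant {self.variant!r}")
        mi = MutualInformation(
            n_bins=self.n_bins, estimator=self.estimator
        ).fit_transform(X)
        mi_df = as_square_frame(mi)
        asu = asu_adjacency(mi_df)
        if self.variant == "asu":
            return asu.to_numpy()
        if self.variant == "auv1":
            return auv1_adjacency(asu).to_numpy()
        return auv2_adjacency(mi_df).to_numpy()


def mi_adjacency_matrix(expr, variant: str = "auv2", n_bins="auto",
                        estimator: str = "miller_madow") -> pd.DataFrame:
    """Entropy-normalized MI adjacency over gene rows of an expression matrix."""
    from ._validation import as_expression_frame, check_no_constant_rows

    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    est = MIAdjacency(variant=variant, n_bins=n_bins, estimator=estimator)
    a = est.fit_transform(df.to_numpy().T)
    return pd.DataFrame(a, index=df.index, columns=df.index)
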