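"""Polynomial and cubic-spline regression R^2 as association measures.

For each ordered gene pair (i, j) the expression of gene j is regressed on
gene i with either a polynomial of degree d (default 3),

    E(y | x) = b0 + b1 x + ... + bd x^d,

or a cubic spline in the truncated-power basis with K knots at equally
spaced interior quantiles of x,

    E(y | x) = b0 + b1 x + b2 x^2 + b3 x^3 + sum_k b_{3+k} (x - knot_k)^3_+,

and the model-fitting index R^2 = cor(y, yhat)^2 is recorded.  Unlike a
correlation, R^2(i -> j) need not equal R^2(j -> i) (a parabola is a
function of x but x is not a function of the parabola), so the matrix is
symmetrized by min, average or max before use as an adjacency; max is the
default since it credits a relationship detected in either direction.

The knot-count rule of thumb is: 5 knots if m > 100, 3 knots if m < 30,
otherwise 4.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import (
    DegenerateInputError,
    ValidationError,
    as_expression_frame,
    check_no_constant_rows,
)

_SYMMETRIZE = ("min", "ave", "max")


def hockey_stick(s):
    """Positive part (s)_+ = max(s, 0), applied component-wise."""
    return np.maximum(np.asarray(s, dtype=float), 0.0) if np.ndim(s) else max(float(s), 0.0)


def auto_knot_count(m: int) -> int:
    """Rule-of-thumb knot count: m > 100 -> 5, m < 30 -> 3, else 4."""
    if m < 10:
        raise ValidationError("spline fitting requires m >= 10")
    if m > 100:
        return 5
    if m < 30:
        return 3
    return 4


def _interior_quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at the k/(K+1) quantiles of x, deduplicated if ties collapse them."""
    q = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(x, q)
    unique = np.unique(knots)
    if unique.size < knots.size:
        warnings.warn(
            f"duplicate knots after quantile placement; reducing from "
            f"{knots.size} to {unique.size} knots",
            stacklevel=3,
        )
    return unique


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def _spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    cols = [_poly_design(x, 3)]
    for k in knots:
        cols.append(hockey_stick(x - k)[:, None] ** 3)
    return np.hstack(cols)


def _r2_from_fit(y: np.ndarray, fitted: np.ndarray) -> float:
    """R^2 = cor(y, yhat)^2; defined as 0 when either side is constant."""
    yc = y - y.mean()
    fc = fitted - fitted.mean()
    denom = np.sqrt((yc @ yc) * (fc @ fc))
    if denom <= 0 or not np.isfinite(denom):
        return 0.0
    r = yc @ fc / denom
    return float(np.clip(r * r, 0.0, 1.0))


def _lstsq(design: np.ndarray, y: np.ndarray):
    """Pseudoinverse least squares with column scaling for conditioning."""
    scale = np.sqrt((design**2).mean(axis=0))
    scale[scale == 0] = 1.0
    beta_scaled, *_ = np.linalg.lstsq(design / scale, y, rcond=None)
    return beta_scaled / scale


@dataclass
class FitResult:
    r_squared: float
    coefficients: np.ndarray
    fitted: np.ndarray


def fit_poly(x, y, degree: int = 3) -> FitResult:
    """Least-squares polynomial fit of y on x with fitting index R^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if degree < 1:
        raise ValidationError("polynomial degree must be >= 1")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor")
    design = _poly_design(x, degree)
    beta = _lstsq(design, y)
    fitted = design @ beta
    return FitResult(_r2_from_fit(y, fitted), beta, fitted)


def fit_spline(x, y, n_knots="auto", knot_values=None) -> FitResult:
    """Truncated-power cubic spline fit of y on x with fitting index R^2.

    Knots default to equally spaced interior quantiles of x; pass
    ``knot_values`` to place them explicitly, or ``n_knots=0`` to reduce to
    a plain cubic polynomial.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor")
    if knot_values is not None:
        knots = np.sort(np.asarray(knot_values, dtype=float))
    else:
        k = auto_knot_count(x.size) if n_knots == "auto" else int(n_knots)
        if k < 0:
            raise ValidationError("n_knots must be >= 0")
        knots = _interior_quantile_knots(x, k) if k else np.empty(0)
    design = _spline_design(x, knots)
    beta = _lstsq(design, y)
    fitted = design @ beta
    return FitResult(_r2_from_fit(y, fitted), beta, fitted)


def symmetrize(S, method: str = "max") -> pd.DataFrame:
    """Symmetrize a square association matrix entry-wise by min, ave or max."""
    from ._validation import as_square_frame

    df = as_square_frame(S)
    if method not in _SYMMETRIZE:
        raise ValidationError(f"unknown symmetrization {method!r}")
    a = df.to_numpy()
    if method == "min":
        out = np.minimum(a, a.T)
    elif method == "max":
        out = np.maximum(a, a.T)
    else:
        out = (a + a.T) / 2.0
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class RegressionAdjacency(TransformerMixin, BaseEstimator):
    """Expression -> symmetrized regression-R^2 adjacency, scikit-learn style.

    ``transform`` maps an (m samples, n genes) array to the (n, n)
    symmetrized R^2 matrix with unit diagonal.  Fits all n targets against
    each predictor at once through an orthonormal basis of the predictor's
    design matrix, so the pairwise sweep is O(n) decompositions rather than
    O(n^2).

    Parameters
    ----------
    model : {"poly", "spline"}
    degree : int
        Polynomial degree (model="poly").
    n_knots : int or "auto"
        Spline knot count (model="spline"); "auto" applies the sample-size
        rule of thumb.
    symmetrize : {"min", "ave", "max"} or None
        None returns the raw directional matrix (R^2 of column j regressed
        on column i at entry (i, j)).
    """

    def __init__(self, model: str = "poly", degree: int = 3, n_knots="auto",
                 symmetrize: str = "max"):
        self.model = model
        self.degree = degree
        self.n_knots = n_knots
        self.symmetrize = symmetrize

    def _validate(self, X) -> np.ndarray:
        if self.model not in ("poly", "spline"):
            raise ValueError(f"unknown regression model {self.model!r}")
        if self.symmetrize is not None and self.symmetrize not in _SYMMETRIZE:
            raise ValueError(f"unknown symmetrization {self.symmetrize!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-d (samples x genes)")
        if np.ptp(X, axis=0).min() == 0:
            bad = np.flatnonzero(np.ptp(X, axis=0) == 0).tolist()
            raise DegenerateInputError(f"constant genes at columns {bad}")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _design(self, x: np.ndarray) -> np.ndarray:
        if self.model == "poly":
            return _poly_design(x, int(self.degree))
        k = auto_knot_count(x.size) if self.n_knots == "auto" else int(self.n_knots)
        knots = _interior_quantile_knots(x, k) if k else np.empty(0)
        return _spline_design(x, knots)

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        m, n = X.shape
        Yc = X - X.mean(axis=0)
        ynorm = np.sqrt((Yc**2).sum(axis=0))
        r2 = np.zeros((n, n))
        for i in range(n):
            design = self._design(X[:, i])
            q, _ = np.linalg.qr(design)
            fitted = q @ (q.T @ X)  # all targets at once
            Fc = fitted - fitted.mean(axis=0)
            fnorm = np.sqrt((Fc**2).sum(axis=0))
            denom = ynorm * fnorm
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.einsum("sj,sj->j", Yc, Fc) / denom
            r[~np.isfinite(r)] = 0.0
            r2[i] = np.clip(r * r, 0.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        if self.symmetrize is not None:
            r2 = symmetrize(r2, self.symmetrize).to_numpy()
        return r2


def r2_matrix(expr, model: str = "poly", degree: int = 3, n_knots="auto",
              symmetrize_method=None) -> pd.DataFrame:
    """Pairwise regression R^2 matrix over gene rows.

    Entry (i, j) is the R^2 of regressing gene j on gene i; pass
    ``symmetrize_method`` ("min"/"ave"/"max") to fold the two directions.
    """
    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    est = RegressionAdjacency(model=model, degree=degree, n_knots=n_knots,
                              symmetrize=symmetrize_method)
    a = est.fit_transform(df.to_numpy().T)
    return pd.DataFrame(a, index=df.index, columns=df.index)
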