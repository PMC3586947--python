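"""Equal-width discretization, entropy estimation and mutual information.

Continuous expression profiles are discretized into R equal-width bins over
[min(x), max(x)], with R = round(sqrt(m)) by default.  Entropies are in nats
(natural log).  Two estimators are provided:

* ``plugin``: H = -sum p_r log p_r with empirical frequencies p_r;
* ``miller_madow``: plugin + (B+ - 1) / (2m), where B+ counts non-empty bins
  (cells, for joint entropy) — a first-order bias correction.

Mutual information is computed through the entropy identity
MI = H(dx) + H(dy) - H(dx, dy) with the chosen estimator applied to each
term, and is clamped at zero from below (the correction terms need not
respect non-negativity).  For the plugin estimator MI equals the multinomial
likelihood-ratio (G) statistic of independence divided by 2m exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import (
    DegenerateInputError,
    ValidationError,
    as_expression_frame,
    check_no_constant_rows,
)

_ESTIMATORS = ("plugin", "miller_madow")


def default_n_bins(m: int) -> int:
    """Default bin count round(sqrt(m)), half away from zero, at least 2."""
    if m < 4:
        raise ValidationError("need m >= 4 samples to choose a bin count")
    return max(2, int(np.floor(np.sqrt(m) + 0.5)))


@dataclass
class DiscretizedVector:
    """Integer bin labels 1..n_bins from equal-width discretization."""

    bins: np.ndarray
    n_bins: int
    bin_edges: np.ndarray


def equal_width_discretize(x, n_bins: int) -> DiscretizedVector:
    """Assign each x_l to one of ``n_bins`` equal-width bins over [min, max].

    Bins are right-open except the last, which is closed at max(x), so every
    observation (including the maximum) gets exactly one label.
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise DegenerateInputError("cannot discretize a constant vector")
    width = (hi - lo) / n_bins
    idx = np.floor((x - lo) / width).astype(int) + 1
    np.clip(idx, 1, n_bins, out=idx)
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = hi
    return DiscretizedVector(bins=idx, n_bins=n_bins, bin_edges=edges)


@dataclass
class EntropyEstimate:
    value: float
    estimator: str
    n_nonempty_bins: int


def _entropy_from_counts(counts: np.ndarray, estimator: str) -> EntropyEstimate:
    if estimator not in _ESTIMATORS:
        raise ValidationError(f"unknown entropy estimator {estimator!r}")
    counts = np.asarray(counts, dtype=float).ravel()
    counts = counts[counts > 0]
    m = counts.sum()
    p = counts / m
    h = float(-(p * np.log(p)).sum())
    b_plus = counts.size
    if estimator == "miller_madow":
        h += (b_plus - 1) / (2.0 * m)
    return EntropyEstimate(value=max(h, 0.0), estimator=estimator,
                           n_nonempty_bins=b_plus)


def _as_labels(dx) -> np.ndarray:
    if isinstance(dx, DiscretizedVector):
        return dx.bins
    return np.asarray(dx, dtype=int).ravel()


def entropy(dx, estimator: str = "plugin") -> EntropyEstimate:
    """Entropy (nats) of a discretized vector's bin-label distribution."""
    labels = _as_labels(dx)
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts, estimator)


def contingency_table(dx, dy) -> np.ndarray:
    """Joint bin-count table of two discretized vectors of equal length."""
    a = _as_labels(dx)
    b = _as_labels(dy)
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    ra = a.max() - a.min() + 1
    rb = b.max() - b.min() + 1
    flat = (a - a.min()) * rb + (b - b.min())
    return np.bincount(flat, minlength=ra * rb).reshape(ra, rb)


def joint_entropy(dx, dy, estimator: str = "plugin") -> EntropyEstimate:
    """Entropy of the joint (dx, dy) cell distribution."""
    return _entropy_from_counts(contingency_table(dx, dy), estimator)


def mutual_information(dx, dy, estimator: str = "plugin") -> float:
    """MI(dx, dy) = H(dx) + H(dy) - H(dx, dy), clamped at 0 from below."""
    hx = entropy(dx, estimator).value
    hy = entropy(dy, estimator).value
    hxy = joint_entropy(dx, dy, estimator).value
    return max(hx + hy - hxy, 0.0)


def lrt_statistic(dx, dy) -> float:
    """Multinomial likelihood-ratio (G) statistic of independence.

    Computed directly from the contingency table as
    2 sum_rc n_rc log(n_rc m / (n_r. n_.c)); equals 2 m MI_plugin exactly.
    """
    table = contingency_table(dx, dy).astype(float)
    m = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * np.log(table * m / (row * col))
    return float(2.0 * np.nansum(terms))


def mi_pvalue(dx, dy) -> float:
    """Asymptotic p-value for MI via the chi-square limit of the G statistic."""
    from scipy import stats

    table = contingency_table(dx, dy)
    r = int((table.sum(axis=1) > 0).sum())
    c = int((table.sum(axis=0) > 0).sum())
    df = max((r - 1) * (c - 1), 1)
    return float(stats.chi2.sf(lrt_statistic(dx, dy), df=df))


class MutualInformation(TransformerMixin, BaseEstimator):
    """Pairwise mutual-information matrix as a scikit-learn transformer.

    ``transform`` maps an (m samples, n genes) array to the symmetric (n, n)
    MI matrix; the diagonal holds each gene's marginal entropy.  Fitted
    attributes after ``transform``-through-``fit_transform`` are exposed by
    `fit` on the same data: ``entropies_`` (per-gene marginal entropies) and
    ``n_bins_`` (the resolved bin count).

    Parameters
    ----------
    n_bins : int or "auto"
        Equal-width bin count; "auto" uses round(sqrt(m)).
    estimator : {"plugin", "miller_madow"}
    """

    def __init__(self, n_bins="auto", estimator: str = "miller_madow"):
        self.n_bins = n_bins
        self.estimator = estimator

    def _resolve_bins(self, m: int) -> int:
        if self.n_bins == "auto":
            return default_n_bins(m)
        n_bins = int(self.n_bins)
        if n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        return n_bins

    def _discretize_all(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-d (samples x genes)")
        if np.ptp(X, axis=0).min() == 0:
            bad = np.flatnonzero(np.ptp(X, axis=0) == 0).tolist()
            raise DegenerateInputError(f"constant genes at columns {bad}")
        r = self._resolve_bins(X.shape[0])
        return np.vstack(
            [equal_width_discretize(X[:, j], r).bins for j in range(X.shape[1])]
        ), r

    def fit(self, X, y=None):
        disc, r = self._discretize_all(X)
        self.n_features_in_ = disc.shape[0]
        self.n_bins_ = r
        self.entropies_ = np.array(
            [entropy(row, self.estimator).value for row in disc]
        )
        return self

    def transform(self, X) -> np.ndarray:
        disc, r = self._discretize_all(X)
        n = disc.shape[0]
        ent = np.array([entropy(row, self.estimator).value for row in disc])
        mi = np.zeros((n, n))
        disc0 = disc - 1  # 0-based labels, all in 0..r-1
        for i in range(n):
            base = disc0[i] * r
            for j in range(i + 1, n):
                counts = np.bincount(base + disc0[j], minlength=r * r)
                h_joint = _entropy_from_counts(counts, self.estimator).value
                mi[i, j] = mi[j, i] = max(ent[i] + ent[j] - h_joint, 0.0)
        np.fill_diagonal(mi, ent)
        return mi


def mi_matrix(expr, n_bins="auto", estimator: str = "miller_madow") -> pd.DataFrame:
    """Pairwise MI matrix over gene rows; diagonal = marginal entropies."""
    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    est = MutualInformation(n_bins=n_bins, estimator=estimator)
    mi = est.fit_transform(df.to_numpy().T)
    return pd.DataFrame(mi, index=df.index, columns=df.index)


def gene_entropies(expr, n_bins="auto", estimator: str = "miller_madow") -> pd.Series:
    """Marginal entropy of each gene row after equal-width discretization."""
    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    est = MutualInformation(n_bins=n_bins, estimator=estimator).fit(
        df.to_numpy().T
    )
    return pd.Series(est.entropies_, index=df.index, name="entropy")
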