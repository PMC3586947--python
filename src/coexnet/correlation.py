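"""Correlation-based association measures.

Implements the Pearson and Spearman correlations and the biweight
midcorrelation (bicor), a robust correlation that replaces mean/variance by
median/MAD and down-weights observations with a Tukey biweight.  For a vector
x with median med(x) and (unscaled) median absolute deviation mad(x),

    u_i = (x_i - med(x)) / (9 mad(x)),
    w_i = (1 - u_i^2)^2  if |u_i| < 1 else 0,

and bicor(x, y) is the cosine similarity of the weighted, median-centred
vectors (x_i - med(x)) w_i(x) and (y_i - med(y)) w_i(y).  Points further than
nine MADs from the median get weight zero; the ``max_p_outliers`` parameter
caps the fraction of points per side of the median that may be zero-weighted,
so that heavy one-sided tails do not discard too much data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import (
    DegenerateInputError,
    ValidationError,
    as_expression_frame,
    as_square_frame,
    check_no_constant_rows,
)

DEFAULT_MAX_P_OUTLIERS = 0.02


def _check_pair(x, y, min_m: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_m:
        raise ValidationError(f"need at least {min_m} samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    return x, y


def pearson_cor(x, y) -> float:
    """Product-moment correlation of two non-constant vectors."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def spearman_cor(x, y) -> float:
    """Pearson correlation of mid-ranks (ties receive their average rank)."""
    x, y = _check_pair(x, y)
    return pearson_cor(stats.rankdata(x), stats.rankdata(y))


def _bicor_terms(x: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Weighted median-centred terms (x_i - med) * w_i for one vector.

    Falls back to mean-centred, unit-weight (Pearson) terms when mad(x) = 0
    but the vector is not constant, since u_i is undefined there.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))  # unscaled MAD, no consistency factor
    if mad == 0.0:
        if np.ptp(x) == 0:
            raise DegenerateInputError("constant vector: bicor undefined")
        return x - x.mean()
    u = (x - med) / (9.0 * mad)
    # Cap the per-side proportion of zero-weight points at max_p_outliers:
    # shrink u on each side of the median so the max_p_outliers quantile
    # keeps |u| <= 1 (and hence nonzero weight).
    q_low = np.quantile(x, max_p_outliers)
    u_low = (q_low - med) / (9.0 * mad)
    if u_low < -1.0:
        u = np.where(u < 0, u / (-u_low), u)
    q_high = np.quantile(x, 1.0 - max_p_outliers)
    u_high = (q_high - med) / (9.0 * mad)
    if u_high > 1.0:
        u = np.where(u > 0, u / u_high, u)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x, y, max_p_outliers: float = DEFAULT_MAX_P_OUTLIERS) -> float:
    """Biweight midcorrelation of two vectors.

    Parameters
    ----------
    x, y : array-like, same length m >= 3
    max_p_outliers : float in (0, 0.5]
        Cap on the proportion of observations per side of the median that
        may receive zero weight (default 0.02).
    """
    if not 0 < max_p_outliers <= 0.5:
        raise ValidationError("max_p_outliers must lie in (0, 0.5]")
    x, y = _check_pair(x, y)
    tx = _bicor_terms(x, max_p_outliers)
    ty = _bicor_terms(y, max_p_outliers)
    denom = np.sqrt((tx @ tx) * (ty @ ty))
    if denom == 0.0:
        raise DegenerateInputError("all observations zero-weighted: bicor undefined")
    return float(np.clip(tx @ ty / denom, -1.0, 1.0))


def cor_pvalue(r: float, m: int) -> float:
    """Two-sided asymptotic p-value for a correlation via the Student-t transform.

    Uses t = r sqrt((m - 2) / (1 - r^2)) with m - 2 degrees of freedom;
    |r| = 1 returns 0.
    """
    if m < 4:
        raise ValidationError("p-value requires m >= 4")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=m - 2))


class Correlation(TransformerMixin, BaseEstimator):
    """Gene-gene correlation matrix as a scikit-learn transformer.

    ``fit`` validates, ``transform`` maps an (m samples, n genes) array to
    the (n, n) signed correlation matrix, so the estimator composes with
    downstream adjacency transformers in a Pipeline.

    Parameters
    ----------
    method : {"pearson", "spearman", "bicor"}
    max_p_outliers : float
        Only used for method="bicor".
    """

    def __init__(self, method: str = "bicor",
                 max_p_outliers: float = DEFAULT_MAX_P_OUTLIERS):
        self.method = method
        self.max_p_outliers = max_p_outliers

    def _validate(self, X) -> np.ndarray:
        if self.method not in ("pearson", "spearman", "bicor"):
            raise ValueError(f"unknown correlation method {self.method!r}")
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

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        genes = X.T  # rows = genes
        if self.method == "spearman":
            genes = np.apply_along_axis(stats.rankdata, 1, genes)
        if self.method in ("pearson", "spearman"):
            terms = genes - genes.mean(axis=1, keepdims=True)
        else:
            terms = np.vstack(
                [_bicor_terms(g, self.max_p_outliers) for g in genes]
            )
        norms = np.sqrt(np.einsum("ij,ij->i", terms, terms))
        if (norms == 0).any():
            bad = np.flatnonzero(norms == 0).tolist()
            raise DegenerateInputError(f"zero-weight genes at columns {bad}")
        c = (terms / norms[:, None]) @ (terms / norms[:, None]).T
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        return c


def cor_matrix(expr, method: str = "pearson",
               max_p_outliers: float = DEFAULT_MAX_P_OUTLIERS) -> pd.DataFrame:
    """Pairwise correlation matrix over the rows (genes) of an expression matrix."""
    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    est = Correlation(method=method, max_p_outliers=max_p_outliers)
    c = est.fit_transform(df.to_numpy().T)
    return pd.DataFrame(c, index=df.index, columns=df.index)


@dataclass
class DiscordantPair:
    """A gene pair where correlation and MI adjacency disagree most strongly."""

    id_a: str
    id_b: str
    z_cor: float
    z_mi: float
    cor_value: float
    mi_adjacency_value: float
    kind: str  # "mi": high Z.MI with low Z.cor; "cor": the converse


def discordance_screen(cor_mat, mi_adj, z_threshold: float = 1.9):
    """Find gene pairs where |cor| and the MI adjacency strongly disagree.

    |cor| and the MI adjacency are standardized across all upper-triangle
    pairs into z-scores (mean 0, sd 1 over the screened set).  Returns the
    pair maximizing the MI z-score among pairs with cor z-score below
    ``z_threshold`` (kind="mi"), and the pair maximizing the cor z-score
    among pairs with MI z-score below the threshold (kind="cor").  Argmax
    ties break lexicographically on (id_a, id_b).
    """
    cor_df = as_square_frame(cor_mat)
    mi_df = as_square_frame(mi_adj)
    if list(cor_df.index) != list(mi_df.index):
        raise ValidationError("correlation and MI matrices must share ids/order")
    n = cor_df.shape[0]
    if n < 2:
        raise ValidationError("discordance screen needs at least 2 genes")
    ids = list(cor_df.index)
    iu, ju = np.triu_indices(n, k=1)
    cors = cor_df.to_numpy()[iu, ju]
    mis = mi_df.to_numpy()[iu, ju]
    abs_cor = np.abs(cors)

    def _standardize(v):
        sd = v.std()
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    z_cor = _standardize(abs_cor)
    z_mi = _standardize(mis)

    def _argmax(score, mask):
        if not mask.any():
            return None
        best = np.max(score[mask])
        cand = np.flatnonzero(mask & (score == best))
        # lexicographic (id_a, id_b) tie-break
        cand = sorted(cand, key=lambda k: (ids[iu[k]], ids[ju[k]]))
        return cand[0]

    out = []
    k = _argmax(z_mi, z_cor < z_threshold)
    if k is not None:
        out.append(DiscordantPair(ids[iu[k]], ids[ju[k]], float(z_cor[k]),
                                  float(z_mi[k]), float(cors[k]), float(mis[k]),
                                  kind="mi"))
    k = _argmax(z_cor, z_mi < z_threshold)
    if k is not None:
        out.append(DiscordantPair(ids[iu[k]], ids[ju[k]], float(z_cor[k]),
                                  float(z_mi[k]), float(cors[k]), float(mis[k]),
                                  kind="cor"))
    return out
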