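"""Module detection by hierarchical clustering of 1 - adjacency.

Genes are clustered with unweighted average linkage (UPGMA) on the
dissimilarity 1 - A, the tree is cut at a fixed height (by default 0.995
times the final merge height), and every resulting branch with at least
``min_module_size`` leaves becomes a module, labeled 1..K in decreasing
size order; all remaining genes are assigned the background label 0.

The same clustering procedure is applied regardless of which association
measure produced the adjacency, so module-recovery comparisons between
measures are not confounded by the clustering step.  Partition agreement is
quantified by the (unadjusted) Rand index: the fraction of gene pairs on
which two partitions agree (clustered together in both, or apart in both),
with the background label treated as an ordinary cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import rand_score

from ._validation import ValidationError, as_square_frame, validate_adjacency

DEFAULT_MIN_MODULE_SIZE = 20
AUTO_CUT_FRACTION = 0.995


def _auto_cut_height(heights: np.ndarray) -> float:
    """Scale-adaptive static cut height for a dendrogram.

    Cuts in the middle of the widest gap between consecutive merge heights
    in the upper half of the tree (heights at or above the median), which
    separates tight branches from the loose top-level joins regardless of
    the dissimilarity's dynamic range.  When the upper half carries no gap
    (e.g. all merges at one height) the cut falls back to 0.995 x the
    maximum merge height.
    """
    h = np.sort(np.asarray(heights, dtype=float))
    top = h[h >= np.median(h)]
    if top.size >= 2:
        gaps = np.diff(top)
        i = int(np.argmax(gaps))
        if gaps[i] > 0:
            return float((top[i] + top[i + 1]) / 2.0)
    return float(AUTO_CUT_FRACTION * h[-1])


def average_linkage(dissim) -> np.ndarray:
    """UPGMA linkage matrix (scipy format) from a square dissimilarity matrix.

    Requires a symmetric matrix with zero diagonal and entries in [0, 1].
    """
    df = as_square_frame(dissim)
    d = df.to_numpy()
    if np.abs(d - d.T).max() > 1e-9:
        raise ValidationError("dissimilarity matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    if d.min() < 0 or d.max() > 1 + 1e-12:
        raise ValidationError("dissimilarities must lie in [0, 1]")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def cut_modules(linkage_matrix: np.ndarray, cut_height="auto",
                min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                ids=None) -> pd.Series:
    """Fixed-height branch cut of a dendrogram into modules.

    Branches whose internal merges all occur below ``cut_height`` and that
    contain at least ``min_module_size`` leaves become modules labeled
    1..K in decreasing size order (ties by branch order); everything else
    gets the background label 0.  ``cut_height="auto"`` places the cut in
    the widest gap between consecutive merge heights in the upper half of
    the tree (see `_auto_cut_height`), which adapts to the dynamic range
    of the dissimilarity measure.
    """
    Z = np.asarray(linkage_matrix, dtype=float)
    n = Z.shape[0] + 1
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    if cut_height == "auto":
        cut_height = _auto_cut_height(Z[:, 2]) if n > 1 else 1.0
    cut_height = float(cut_height)
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(flat).value_counts()
    kept = sizes[sizes >= min_module_size]
    # decreasing size; ties broken by original flat-cluster id for determinism
    order = sorted(kept.index, key=lambda c: (-kept[c], c))
    for new, orig in enumerate(order, start=1):
        labels[flat == orig] = new
    if ids is None:
        ids = [f"g{i + 1}" for i in range(n)]
    return pd.Series(labels, index=list(ids), name="module")


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index between two partitions of the same genes.

    Label 0 (background) is treated as an ordinary cluster label.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValidationError("partitions must cover the same genes")
    return float(rand_score(a.to_numpy(), b.to_numpy()))


class HierarchicalModules(ClusterMixin, BaseEstimator):
    """Average-linkage module detector over an adjacency matrix.

    ``fit`` takes an (n, n) adjacency (values in [0, 1], unit diagonal),
    clusters 1 - A with UPGMA and cuts the tree; fitted attributes are
    ``linkage_`` (scipy linkage matrix) and ``labels_`` (module labels with
    0 = background).

    Parameters
    ----------
    cut_height : float or "auto"
        Tree cut height; "auto" is 0.995 x the final merge height.
    min_module_size : int
        Minimum branch size to be reported as a module (default 20).
    """

    def __init__(self, cut_height="auto",
                 min_module_size: int = DEFAULT_MIN_MODULE_SIZE):
        self.cut_height = cut_height
        self.min_module_size = min_module_size

    def fit(self, X, y=None):
        adj = validate_adjacency(X, tol=1e-8)
        d = 1.0 - adj.to_numpy()
        np.fill_diagonal(d, 0.0)
        self.n_features_in_ = d.shape[1]
        self.linkage_ = average_linkage(d)
        self.labels_ = cut_modules(
            self.linkage_, cut_height=self.cut_height,
            min_module_size=self.min_module_size,
        ).to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


MEASURES = (
    "bicor-tom", "bicor-signed", "bicor-unsigned", "pearson-signed",
    "asu", "auv1", "auv2", "poly", "spline",
    "relnet", "clr", "mrnet", "aracne",
)


def adjacency_for_measure(expr, measure: str, n_bins="auto",
                          estimator: str = "miller_madow",
                          max_p_outliers: float = 0.02,
                          beta_signed: float = 12.0,
                          beta_unsigned: float = 6.0,
                          degree: int = 3, n_knots="auto",
                          symmetrize: str = "max",
                          tau: float = 0.0,
                          dpi_tolerance: float = 0.0) -> pd.DataFrame:
    """Build the adjacency matrix for one named co-expression measure."""
    from ._validation import as_expression_frame, check_no_constant_rows
    from .correlation import cor_matrix
    from .information import mi_matrix
    from .inference import MINetworkInference
    from .mi_adjacency import mi_adjacency_matrix
    from .regression import r2_matrix
    from .transforms import soft_adjacency, tom

    df = as_expression_frame(expr)
    check_no_constant_rows(df)
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    if measure.startswith("bicor") or measure == "pearson-signed":
        method = "pearson" if measure.startswith("pearson") else "bicor"
        c = cor_matrix(df, method=method, max_p_outliers=max_p_outliers)
        if measure == "bicor-unsigned":
            return soft_adjacency(c, mode="unsigned", beta=beta_unsigned)
        signed = soft_adjacency(c, mode="signed", beta=beta_signed)
        if measure == "bicor-tom":
            return tom(signed)
        return signed
    if measure in ("asu", "auv1", "auv2"):
        return mi_adjacency_matrix(df, variant=measure, n_bins=n_bins,
                                   estimator=estimator)
    if measure in ("poly", "spline"):
        a = r2_matrix(df, model=measure, degree=degree, n_knots=n_knots,
                      symmetrize_method=symmetrize)
        out = a.to_numpy()
        np.fill_diagonal(out, 1.0)
        return pd.DataFrame(out, index=a.index, columns=a.columns)
    # MI inference algorithms
    mi = mi_matrix(df, n_bins=n_bins, estimator=estimator)
    inf = MINetworkInference(method=measure, tau=tau,
                             dpi_tolerance=dpi_tolerance)
    a = inf.fit_transform(mi)
    return pd.DataFrame(a, index=df.index, columns=df.index)


def modules_pipeline(expr, measure: str = "bicor-tom", cut_height="auto",
                     min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                     **measure_kwargs) -> pd.Series:
    """Expression -> adjacency -> 1 - A -> UPGMA -> branch cut, in one call.

    The clustering settings (cut height, minimum module size, linkage) are
    identical for every measure, so differences in recovered modules
    reflect the association measure alone.
    """
    adj = adjacency_for_measure(expr, measure, **measure_kwargs)
    det = HierarchicalModules(cut_height=cut_height,
                              min_module_size=min_module_size)
    det.fit(adj.to_numpy())
    return pd.Series(det.labels_, index=adj.index, name="module")
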