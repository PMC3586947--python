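"""Independent brute-force reference implementations used across the tests.

Every function here is a literal, unoptimized transcription of the defining
formula, written without reference to the package internals, so agreement
between package and oracle is evidence of correctness rather than of shared
code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_oracle(x, y):
    x = np.asarray(x, float); y = np.asarray(y, float)
    m = len(x)
    sx, sy = x.sum(), y.sum()
    num = m * (x * y).sum() - sx * sy
    den = math.sqrt(m * (x * x).sum() - sx * sx) * math.sqrt(m * (y * y).sum() - sy * sy)
    return num / den


def bicor_oracle(x, y):
    """Literal biweight midcorrelation, no outlier-proportion capping."""
    x = np.asarray(x, float); y = np.asarray(y, float)

    def terms(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * ((1 - np.abs(u)) > 0)
        return (v - med) * w

    tx, ty = terms(x), terms(y)
    return (tx * ty).sum() / math.sqrt((tx * tx).sum() * (ty * ty).sum())


def mi_plugin_oracle(table):
    """Direct double-sum MI over a joint count table (nats)."""
    table = np.asarray(table, float)
    m = table.sum()
    p = table / m
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    total = 0.0
    for r in range(p.shape[0]):
        for c in range(p.shape[1]):
            if p[r, c] > 0:
                total += p[r, c] * math.log(p[r, c] / (pr[r] * pc[c]))
    return total


def entropy_oracle(counts, miller_madow=False):
    counts = np.asarray(counts, float).ravel()
    m = counts.sum()
    h = -sum(c / m * math.log(c / m) for c in counts if c > 0)
    if miller_madow:
        h += ((counts > 0).sum() - 1) / (2 * m)
    return h


def tom_oracle(a):
    """Triple-loop topological overlap."""
    a = np.asarray(a, float)
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, l] * a[l, j] for l in range(n) if l not in (i, j))
            ki = sum(a[i, l] for l in range(n) if l != i)
            kj = sum(a[j, l] for l in range(n) if l != j)
            t[i, j] = (shared + a[i, j]) / (min(ki, kj) - a[i, j] + 1)
    return t


def clr_oracle(mi):
    """Per-pair loop CLR with sample-sd row statistics."""
    mi = np.asarray(mi, float)
    n = mi.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            row_i = [mi[i, k] for k in range(n) if k != i]
            row_j = [mi[j, k] for k in range(n) if k != j]
            zi = max(0.0, (mi[i, j] - np.mean(row_i)) / np.std(row_i, ddof=1))
            zj = max(0.0, (mi[i, j] - np.mean(row_j)) / np.std(row_j, ddof=1))
            out[i, j] = math.sqrt(zi**2 + zj**2)
    return out


def mrnet_oracle(mi):
    """Exhaustive MRMR forward selection for every target."""
    mi = np.asarray(mi, float)
    n = mi.shape[0]
    directional = np.zeros((n, n))
    for target in range(n):
        remaining = [j for j in range(n) if j != target]
        selected = []
        while remaining:
            best_j, best_score = None, -np.inf
            for j in remaining:
                if selected:
                    score = mi[j, target] - np.mean([mi[j, s] for s in selected])
                else:
                    score = mi[j, target]
                if score > best_score:  # strict: first max wins ties
                    best_j, best_score = j, score
            directional[target, best_j] = best_score
            selected.append(best_j)
            remaining.remove(best_j)
    out = np.maximum(directional, directional.T)
    return np.maximum(out, 0.0) * (1 - np.eye(n))


def aracne_oracle(mi, tau=0.0, tolerance=0.0):
    """All-triplets DPI with simultaneous removal."""
    mi = np.asarray(mi, float).copy()
    n = mi.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and mi[i, j] <= tau:
                mi[i, j] = 0.0
    flagged = set()
    for i, j, k in itertools.permutations(range(n), 3):
        if i < j and mi[i, j] > 0 and mi[i, k] > 0 and mi[k, j] > 0:
            if mi[i, j] <= min(mi[i, k], mi[k, j]) - tolerance:
                flagged.add((i, j))
    for i, j in flagged:
        mi[i, j] = mi[j, i] = 0.0
    return mi


def upgma_oracle(d):
    """Naive UPGMA agglomeration; returns the sorted list of merge heights."""
    d = np.asarray(d, float).copy()
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            avg = np.mean([d[x, y] for x in clusters[a] for y in clusters[b]])
            if best is None or avg < best[0]:
                best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def lstsq_r2_oracle(design, y):
    """Normal-equations least squares and R^2 = cor(y, yhat)^2."""
    design = np.asarray(design, float)
    y = np.asarray(y, float)
    beta = np.linalg.pinv(design.T @ design) @ design.T @ y
    fitted = design @ beta
    return pearson_oracle(y, fitted) ** 2


def rand_index_oracle(a, b):
    a = list(a); b = list(b)
    agree = total = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        together_a = a[i] == a[j]
        together_b = b[i] == b[j]
        agree += together_a == together_b
        total += 1
    return agree / total
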