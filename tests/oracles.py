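"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the sigmoid oracle scans
a (slope, half-rise-time) grid solving the remaining two parameters by
linear least squares; the k-means oracle enumerates every assignment; the
OLS oracle applies the normal equations; the hypergeometric oracle sums the
tail explicitly.
"""

import itertools
import math

import numpy as np


def sigmoid_grid_oracle(t, y, c_grid=None, ti_grid=None):
    """Minimum-RSS sigmoid fit over a (c, t_i) grid.

    For fixed c and t_i the model ``a - b * s(t)`` with
    ``s = 1/(1+exp(c(t-t_i)))`` is linear in (a, b), so the inner problem is
    solved exactly by least squares. Returns (a, b, c, t_i, rss).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if c_grid is None:
        c_grid = np.arange(0.25, 4.0 + 1e-9, 0.25)
    if ti_grid is None:
        ti_grid = np.arange(0.0, 20.0 + 1e-9, 0.1)
    best = None
    for c in c_grid:
        for t_i in ti_grid:
            s = 1.0 / (1.0 + np.exp(np.clip(c * (t - t_i), -700, 700)))
            design = np.column_stack([np.ones_like(t), -s])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((design @ coef - y) ** 2))
            if best is None or rss < best[4]:
                best = (float(coef[0]), float(coef[1]), float(c), float(t_i), rss)
    return best


def ols_normal_equations(x, y):
    """Closed-form simple-regression intercept and slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    return ybar - slope * xbar, slope


def exhaustive_min_inertia_partition(profiles, k):
    """Globally optimal k-means partition by enumerating all k^n assignments.

    Returns the partition as a set of frozensets of row indices. Vectorised:
    inertia of an assignment is sum ||x||^2 - sum_j ||sum_members||^2 / n_j.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    assignments = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int64)
    onehot = np.eye(k)[assignments]  # (m, n, k)
    counts = onehot.sum(axis=1)  # (m, k)
    sums = np.einsum("mnk,nd->mkd", onehot, profiles)
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(counts > 0, (sums**2).sum(axis=2) / np.where(counts > 0, counts, 1), 0.0)
    inertia = (profiles**2).sum() - reduction.sum(axis=1)
    best = assignments[int(np.argmin(inertia))]
    return partition_of(best), float(inertia.min())


def partition_of(labels):
    """Cluster labels -> relabelling-invariant partition (set of frozensets)."""
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == j).tolist()) for j in np.unique(labels)}


def hypergeom_tail(k, M, K, N):
    """P[X >= k] for X ~ Hypergeometric(M, K, N) by direct summation."""
    total = 0.0
    for i in range(k, min(K, N) + 1):
        total += math.comb(K, i) * math.comb(M - K, N - i) / math.comb(M, N)
    return total


def sorted_quantile(values, q):
    """Linear-interpolation quantile computed from an explicit sort."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (v.size - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def pearson_by_hand(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def spearman_by_hand(x, y):
    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    return pearson_by_hand(average_ranks(x), average_ranks(y))
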