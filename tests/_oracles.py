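"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written directly from the textbook definition of the
quantity it computes and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN: core point = at least min_pts points (self
    included) within eps; clusters grow by density-reachability from
    cores; unreachable points are noise (-1)."""
    n = len(points)
    UNVISITED, NOISE = -2, -1
    labels = np.full(n, UNVISITED)
    close = squareform(pdist(points)) <= eps if n > 1 else np.ones((n, n), bool)
    np.fill_diagonal(close, True)
    neighbors = [np.flatnonzero(close[i]) for i in range(n)]
    cid = 0
    for i in range(n):
        if labels[i] != UNVISITED:
            continue
        if neighbors[i].size < min_pts:
            labels[i] = NOISE
            continue
        labels[i] = cid
        seeds = list(neighbors[i])
        k = 0
        while k < len(seeds):
            q = seeds[k]
            k += 1
            if labels[q] == NOISE:
                labels[q] = cid  # border point
            if labels[q] != UNVISITED:
                continue
            labels[q] = cid
            if neighbors[q].size >= min_pts:
                seeds.extend(neighbors[q])
        cid += 1
    return labels


def partition_of(labels: np.ndarray) -> tuple[frozenset, frozenset]:
    """(set of clusters as frozensets of indices, noise set) for
    label-permutation-invariant comparison."""
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == c).tolist())
        for c in set(labels.tolist())
        if c >= 0
    )
    noise = frozenset(np.flatnonzero(labels == -1).tolist())
    return clusters, noise


def brute_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition:
    adjusted p_(i) = min over j >= i of m * p_(j) / j, capped at 1."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def mixed_anova_ss(values: np.ndarray) -> dict[str, tuple[float, float, float]]:
    """Classical sums-of-squares decomposition of a balanced 2x2 mixed
    design. ``values`` has shape (n_groups, n_subjects, n_within).
    Returns effect -> (F, df1, df2) plus partial eta squared."""
    g, s, w = values.shape
    grand = values.mean()
    group_means = values.mean(axis=(1, 2))
    within_means = values.mean(axis=(0, 1))
    cell_means = values.mean(axis=1)  # (g, w)
    subj_means = values.mean(axis=2)  # (g, s)
    ss_group = s * w * np.sum((group_means - grand) ** 2)
    ss_subj = w * np.sum((subj_means - group_means[:, None]) ** 2)
    ss_within = g * s * np.sum((within_means - grand) ** 2)
    ss_inter = s * np.sum(
        (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
    )
    ss_err = np.sum(
        (
            values
            - subj_means[:, :, None]
            - cell_means[:, None, :]
            + group_means[:, None, None]
        )
        ** 2
    )
    df_group, df_subj = g - 1, g * (s - 1)
    df_within = w - 1
    df_inter = (g - 1) * (w - 1)
    df_err = g * (s - 1) * (w - 1)
    out = {}
    out["group"] = (
        (ss_group / df_group) / (ss_subj / df_subj),
        df_group,
        df_subj,
        ss_group / (ss_group + ss_subj),
    )
    out["within"] = (
        (ss_within / df_within) / (ss_err / df_err),
        df_within,
        df_err,
        ss_within / (ss_within + ss_err),
    )
    out["interaction"] = (
        (ss_inter / df_inter) / (ss_err / df_err),
        df_inter,
        df_err,
        ss_inter / (ss_inter + ss_err),
    )
    return out


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, coded independently."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)


def lyapunov_cov(A1: np.ndarray, sigma: np.ndarray, iters: int = 2000) -> np.ndarray:
    """Stationary covariance of a VAR(1) by fixed-point iteration of
    G = A G A' + Sigma (discrete Lyapunov equation)."""
    G = np.array(sigma, float)
    for _ in range(iters):
        G = A1 @ G @ A1.T + sigma
    return G
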