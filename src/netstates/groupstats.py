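"""Between-group inference: permutation t-tests, Bartlett variance tests,
and TFCE family-wise-error correction for channel-wise maps.

Group differences are assessed with Welch t-statistics whose null
distribution comes from random (or exhaustive, when feasible) permutation of
the group labels.  Channel-wise map comparisons are corrected for multiple
comparisons by threshold-free cluster enhancement (TFCE) followed by
max-statistic permutation, which controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse, stats


__all__ = [
    "GroupResult",
    "welch_t",
    "permutation_ttest",
    "bartlett_test",
    "tfce",
    "fwe_map_test",
    "adjacency_from_topographies",
]


@dataclass
class GroupResult:
    """Outcome of a permutation comparison."""

    t: np.ndarray | float
    p: np.ndarray | float
    p_corrected: np.ndarray | None
    n_perm: int
    seed: int | None
    exhaustive: bool = False


def welch_t(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Welch (unequal-variance) t-statistic along ``axis``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    va = a.var(axis=axis, ddof=1) / na
    vb = b.var(axis=axis, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = a.mean(axis=axis) - b.mean(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        return diff / denom


def _label_splits(n: int, na: int, n_perm: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Index sets assigned to group a under each permutation.

    Exhaustive when the number of arrangements fits within ``n_perm``;
    otherwise Monte-Carlo without the identity guaranteed.
    """
    total = comb(n, na)
    if total <= n_perm:
        splits = np.array(list(combinations(range(n), na)), dtype=np.int64)
        return splits, True
    splits = np.empty((n_perm, na), dtype=np.int64)
    for i in range(n_perm):
        splits[i] = rng.permutation(n)[:na]
    return splits, False


def permutation_ttest(values_a: np.ndarray, values_b: np.ndarray,
                      n_perm: int = 10000, seed: int | None = None) -> GroupResult:
    """Two-sided permutation test on the Welch t-statistic.

    When all ``C(n, n_a)`` label arrangements fit within ``n_perm`` they are
    enumerated and ``p = #{|t_perm| >= |t_obs|} / n_arrangements`` (the
    observed split is one of them); otherwise ``n_perm`` random relabelings
    are drawn and ``p = (1 + #) / (1 + n_perm)``.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    pooled = np.concatenate((a, b))
    n, na = pooled.size, a.size
    t_obs = float(welch_t(a, b))
    rng = np.random.default_rng(seed)
    splits, exhaustive = _label_splits(n, na, n_perm, rng)
    mask = np.zeros((splits.shape[0], n), dtype=bool)
    mask[np.arange(splits.shape[0])[:, None], splits] = True
    t_null = np.array([welch_t(pooled[m], pooled[~m]) for m in mask])
    hits = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    if exhaustive:
        p = hits / splits.shape[0]
    else:
        p = (1 + hits) / (1 + splits.shape[0])
    return GroupResult(t=t_obs, p=p, p_corrected=None,
                       n_perm=splits.shape[0], seed=seed, exhaustive=exhaustive)


def bartlett_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Bartlett's test of equal inter-participant variance (chi-squared)."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 or b.var(ddof=1) == 0:
        raise ValueError("zero variance group")
    stat, p = stats.bartlett(a, b)
    return float(stat), float(p)


def _enhance_positive(x: np.ndarray, edges: np.ndarray, e: float,
                      h: float, dh: float) -> np.ndarray:
    out = np.zeros_like(x)
    hmax = x.max()
    if hmax <= 0:
        return out
    n = x.size
    parent = np.empty(n, dtype=np.int64)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    level = dh / 2.0
    while level < hmax:
        supra = x >= level
        parent[:] = np.arange(n)
        if edges.size:
            both = supra[edges[:, 0]] & supra[edges[:, 1]]
            for i, j in edges[both]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
        roots = np.array([find(i) for i in np.flatnonzero(supra)])
        if roots.size:
            sizes = np.bincount(roots, minlength=n)
            idx = np.flatnonzero(supra)
            out[idx] += sizes[roots] ** e * level ** h * dh
        level += dh
    return out


def tfce(stat_map: np.ndarray, adjacency, E: float = 0.5, H: float = 2.0,
         dh: float | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a channel statistic map.

    For each channel the suprathreshold cluster extent is integrated over
    thresholds: ``sum_h extent(h)^E * h^H * dh``.  Negative values are
    enhanced on their own sign (two-sided application).  ``dh`` defaults to
    ``max|stat|/100``.
    """
    x = np.asarray(stat_map, dtype=float)
    edges = _edge_list(adjacency, x.size)
    amax = np.max(np.abs(x))
    if amax == 0:
        return np.zeros_like(x)
    if dh is None:
        dh = amax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _enhance_positive(np.clip(x, 0, None), edges, E, H, dh)
    neg = _enhance_positive(np.clip(-x, 0, None), edges, E, H, dh)
    return pos - neg


def _edge_list(adjacency, n: int) -> np.ndarray:
    adj = sparse.csr_matrix(adjacency)
    if adj.shape != (n, n):
        raise ValueError("adjacency shape does not match map length")
    if (adj != adj.T).nnz:
        raise ValueError("adjacency must be symmetric")
    coo = sparse.triu(adj, k=1).tocoo()
    return np.column_stack((coo.row, coo.col)).astype(np.int64)


def fwe_map_test(maps_a: np.ndarray, maps_b: np.ndarray, adjacency,
                 n_perm: int = 1000, seed: int | None = None,
                 E: float = 0.5, H: float = 2.0,
                 dh: float | None = None) -> GroupResult:
    """Channel-wise group map comparison with TFCE-FWE correction.

    ``maps_a``/``maps_b`` are ``(n_subjects, M)`` per-channel coefficients.
    The observed Welch t-map is TFCE-enhanced; corrected p-values come from
    the permutation distribution of the maximum absolute enhanced statistic
    (max-statistic correction controls the family-wise error rate).
    Uncorrected p-values use each channel's own permutation t distribution.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("map shapes differ between groups")
    pooled = np.vstack((a, b))
    n, na = pooled.shape[0], a.shape[0]
    t_obs = welch_t(a, b)
    edges = _edge_list(adjacency, t_obs.size)

    def _tfce(stat):
        amax = np.max(np.abs(stat))
        if amax == 0:
            return np.zeros_like(stat)
        step = dh if dh is not None else amax / 100.0
        return (_enhance_positive(np.clip(stat, 0, None), edges, E, H, step)
                - _enhance_positive(np.clip(-stat, 0, None), edges, E, H, step))

    e_obs = _tfce(t_obs)
    rng = np.random.default_rng(seed)
    splits, exhaustive = _label_splits(n, na, n_perm, rng)
    n_used = splits.shape[0]
    max_null = np.empty(n_used)
    t_hits = np.zeros(t_obs.size)
    for i in range(n_used):
        m = np.zeros(n, dtype=bool)
        m[splits[i]] = True
        t_perm = welch_t(pooled[m], pooled[~m])
        e_perm = _tfce(t_perm)
        max_null[i] = np.max(np.abs(e_perm))
        t_hits += np.abs(t_perm) >= np.abs(t_obs) - 1e-12
    if exhaustive:
        p_unc = t_hits / n_used
        p_corr = np.array([np.sum(max_null >= abs(e) - 1e-12) / n_used
                           for e in e_obs])
    else:
        p_unc = (1 + t_hits) / (1 + n_used)
        p_corr = np.array([(1 + np.sum(max_null >= abs(e) - 1e-12)) / (1 + n_used)
                           for e in e_obs])
    p_corr = np.maximum(p_corr, p_unc)  # corrected never below uncorrected
    return GroupResult(t=t_obs, p=p_unc, p_corrected=p_corr,
                       n_perm=n_used, seed=seed, exhaustive=exhaustive)


def adjacency_from_topographies(topographies: np.ndarray) -> np.ndarray:
    """Channel adjacency: channels are neighbours when they load on a common
    planted state (the synthetic topography blocks define the spatial
    neighbourhoods).  Returns a dense symmetric 0/1 matrix, zero diagonal.
    """
    topo = np.asarray(topographies, dtype=float)
    on = (topo > 0).astype(float)
    adj = (on.T @ on) > 0
    np.fill_diagonal(adj, False)
    return adj.astype(np.int8)
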