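"""Numba kernels for the HMM recursions (log-domain, no underflow)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logsumexp_row(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - m)
    return m + np.log(s)


@njit(cache=True)
def forward_backward(log_a, log_pi, log_b):
    """Log-domain forward-backward.

    Returns (log_likelihood, gamma, xi_sum) where gamma is (T, K) posterior
    state probabilities and xi_sum the (K, K) expected transition counts.
    """
    t_len, k = log_b.shape
    alpha = np.empty((t_len, k))
    beta = np.empty((t_len, k))
    work = np.empty(k)
    for j in range(k):
        alpha[0, j] = log_pi[j] + log_b[0, j]
    for t in range(1, t_len):
        for j in range(k):
            for i in range(k):
                work[i] = alpha[t - 1, i] + log_a[i, j]
            alpha[t, j] = _logsumexp_row(work) + log_b[t, j]
    ll = _logsumexp_row(alpha[t_len - 1])
    for j in range(k):
        beta[t_len - 1, j] = 0.0
    for t in range(t_len - 2, -1, -1):
        for i in range(k):
            for j in range(k):
                work[j] = log_a[i, j] + log_b[t + 1, j] + beta[t + 1, j]
            beta[t, i] = _logsumexp_row(work)
    gamma = np.empty((t_len, k))
    for t in range(t_len):
        norm = _logsumexp_row(alpha[t] + beta[t])
        for j in range(k):
            gamma[t, j] = np.exp(alpha[t, j] + beta[t, j] - norm)
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 1):
        for i in range(k):
            for j in range(k):
                xi_sum[i, j] += np.exp(
                    alpha[t, i] + log_a[i, j] + log_b[t + 1, j]
                    + beta[t + 1, j] - ll
                )
    return ll, gamma, xi_sum


@njit(cache=True)
def viterbi(log_a, log_pi, log_b):
    """Most probable state path (0-based); ties break toward the lower index."""
    t_len, k = log_b.shape
    delta = np.empty((t_len, k))
    back = np.zeros((t_len, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = log_pi[j] + log_b[0, j]
    for t in range(1, t_len):
        for j in range(k):
            best = delta[t - 1, 0] + log_a[0, j]
            arg = 0
            for i in range(1, k):
                v = delta[t - 1, i] + log_a[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            back[t, j] = arg
    best = delta[t_len - 1, 0]
    s = 0
    for j in range(1, k):
        if delta[t_len - 1, j] > best:
            best = delta[t_len - 1, j]
            s = j
    path = np.empty(t_len, dtype=np.int64)
    path[t_len - 1] = s
    for t in range(t_len - 2, -1, -1):
        s = back[t + 1, s]
        path[t] = s
    return path
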