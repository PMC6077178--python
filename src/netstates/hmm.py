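"""K-state hidden Markov model with multivariate-Gaussian observations.

Each state is a full-covariance Gaussian over the M channel envelopes; the
latent chain is first-order Markov.  Fitting is maximum-likelihood EM
(Baum-Welch) over the concatenated group envelope matrix, with multiple
seeded restarts; the best-scoring restart is kept.  Decoding uses the
Viterbi algorithm in the log domain.

State labels in decoded paths are 1-based (1..K), matching the convention
used for planted states and reported metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from ._kernels import forward_backward as _fb_kernel
from ._kernels import viterbi as _viterbi_kernel

__all__ = [
    "HMMParams",
    "fit_hmm",
    "viterbi_decode",
    "state_indicators",
    "match_states",
    "forward_backward",
]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """Fitted model: per-state Gaussians plus the switching chain."""

    means: np.ndarray      # (K, M)
    covars: np.ndarray     # (K, M, M) symmetric positive-definite
    transmat: np.ndarray   # (K, K) row-stochastic
    startprob: np.ndarray  # (K,)
    score: float = np.nan  # total log-likelihood of the training data
    n_restarts: int = 1
    seed: int | None = None
    trace: list = field(default_factory=list)  # per-iteration log-likelihood

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def M(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        if np.max(np.abs(self.transmat.sum(axis=1) - 1)) > atol:
            raise ValueError("transition-matrix rows must sum to 1")
        if abs(self.startprob.sum() - 1) > atol:
            raise ValueError("initial distribution must sum to 1")
        for k in range(self.K):
            c = self.covars[k]
            if np.max(np.abs(c - c.T)) > atol:
                raise ValueError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise ValueError(f"covariance {k} not positive-definite")


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at each row of x, via Cholesky."""
    m = x.shape[1]
    chol = linalg.cholesky(cov, lower=True)
    sol = linalg.solve_triangular(chol, (x - mean).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (m * _LOG2PI + logdet + np.einsum("mt,mt->t", sol, sol))


def _log_emissions(x: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    t, k = x.shape[0], means.shape[0]
    out = np.empty((t, k))
    for j in range(k):
        out[:, j] = _log_gaussian(x, means[j], covars[j])
    return out


def _regularize(cov: np.ndarray, ridge: float, floor: float) -> np.ndarray:
    """Ridge toward the mean diagonal; eigenvalue floor if still indefinite."""
    m = cov.shape[0]
    cov = cov + ridge * np.trace(cov) / m * np.eye(m)
    try:
        linalg.cholesky(cov, lower=True)
        return cov
    except linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        log.warning("covariance collapse: flooring eigenvalues (min %.3e)", w[0])
        w = np.maximum(w, floor)
        return v @ np.diag(w) @ v.T


def _m_step(x: np.ndarray, gamma: np.ndarray, xi_sum: np.ndarray,
            ridge: float, floor: float, rng: np.random.Generator):
    t, m = x.shape
    k = gamma.shape[1]
    weights = gamma.sum(axis=0)
    means = np.empty((k, m))
    covars = np.empty((k, m, m))
    global_cov = np.cov(x.T) + ridge * np.eye(m)
    for j in range(k):
        if weights[j] < 1e-6 * t:
            # dead state: re-seed from a random observation
            log.warning("state %d collapsed (weight %.3g); re-seeding", j + 1, weights[j])
            means[j] = x[rng.integers(t)]
            covars[j] = global_cov
            continue
        means[j] = gamma[:, j] @ x / weights[j]
        xc = x - means[j]
        covars[j] = (xc * gamma[:, j, None]).T @ xc / weights[j]
        covars[j] = _regularize(covars[j], ridge, floor)
    transmat = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
    startprob = np.maximum(gamma[0], 1e-300)
    startprob /= startprob.sum()
    return means, covars, transmat, startprob


def _init_from_assignment(x: np.ndarray, k: int, rng: np.random.Generator,
                          ridge: float, floor: float):
    """Random assignment of time points to states; moments per state."""
    t, m = x.shape
    labels = rng.integers(k, size=t)
    means = np.empty((k, m))
    covars = np.empty((k, m, m))
    for j in range(k):
        sel = x[labels == j]
        if sel.shape[0] < m + 2:
            sel = x[rng.integers(t, size=max(m + 2, t // k))]
        means[j] = sel.mean(axis=0)
        covars[j] = _regularize(np.cov(sel.T), ridge, floor)
    transmat = np.full((k, k), 1.0 / k)
    startprob = np.full(k, 1.0 / k)
    return means, covars, transmat, startprob


def _em_run(x, means, covars, transmat, startprob, n_iter, tol, ridge, floor, rng):
    trace = []
    ll_prev = -np.inf
    for _ in range(n_iter):
        log_b = _log_emissions(x, means, covars)
        ll, gamma, xi_sum = _fb_kernel(np.log(np.maximum(transmat, 1e-300)),
                                       np.log(np.maximum(startprob, 1e-300)),
                                       log_b)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll):
            break
        ll_prev = ll
        means, covars, transmat, startprob = _m_step(
            x, gamma, xi_sum, ridge, floor, rng)
    return means, covars, transmat, startprob, trace


def fit_hmm(
    data: np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    restart_iter: int = 15,
    ridge: float = 1e-6,
    eig_floor: float = 1e-10,
) -> HMMParams:
    """Fit the K-state Gaussian HMM to a concatenated ``(T, M)`` matrix.

    Each of ``n_restarts`` seeded restarts initializes from a random
    assignment of time points to states and runs a short EM burn-in
    (``restart_iter`` iterations); the restart with the highest
    log-likelihood is then run to convergence (relative log-likelihood
    change below ``tol`` or ``max_iter`` iterations).  Covariances are
    ridge-regularized (``ridge`` x mean diagonal) every M-step.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be (T, M)")
    if K < 1:
        raise ValueError("K must be at least 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains non-finite values")
    t, m = x.shape
    if K == 1:
        # degenerate model: exact closed form
        mean = x.mean(axis=0, keepdims=True)
        cov = np.atleast_2d(np.cov(x.T, bias=True)).reshape(1, m, m)
        params = HMMParams(mean, cov, np.ones((1, 1)), np.ones(1),
                           n_restarts=n_restarts, seed=seed)
        params.score = float(np.sum(_log_gaussian(x, mean[0],
                                                  _regularize(cov[0], 0.0, eig_floor))))
        params.trace = [params.score]
        return params

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_restarts + 1)]
    best = None
    for r in range(n_restarts):
        init = _init_from_assignment(x, K, rngs[r], ridge, eig_floor)
        fitted = _em_run(x, *init, min(restart_iter, max_iter), tol,
                         ridge, eig_floor, rngs[r])
        if best is None or fitted[4][-1] > best[4][-1]:
            best = fitted
    means, covars, transmat, startprob, trace = best
    if max_iter > restart_iter:
        means, covars, transmat, startprob, tail = _em_run(
            x, means, covars, transmat, startprob,
            max_iter - restart_iter, tol, ridge, eig_floor, rngs[-1])
        trace = trace + tail
    params = HMMParams(means, covars, transmat, startprob,
                       score=trace[-1], n_restarts=n_restarts, seed=seed,
                       trace=trace)
    return params


def forward_backward(params: HMMParams, data: np.ndarray):
    """Posterior state probabilities.

    Returns ``(log_likelihood, gamma)`` with ``gamma`` of shape (T, K),
    rows summing to 1.
    """
    x = np.asarray(data, dtype=float)
    if x.shape[1] != params.M:
        raise ValueError(f"data has {x.shape[1]} channels, model expects {params.M}")
    log_b = _log_emissions(x, params.means, params.covars)
    ll, gamma, _ = _fb_kernel(np.log(np.maximum(params.transmat, 1e-300)),
                              np.log(np.maximum(params.startprob, 1e-300)), log_b)
    return ll, gamma


def viterbi_decode(params: HMMParams, data: np.ndarray) -> np.ndarray:
    """Globally most probable state path, labels 1..K."""
    x = np.asarray(data, dtype=float)
    if x.shape[1] != params.M:
        raise ValueError(f"data has {x.shape[1]} channels, model expects {params.M}")
    log_b = _log_emissions(x, params.means, params.covars)
    path = _viterbi_kernel(np.log(np.maximum(params.transmat, 1e-300)),
                           np.log(np.maximum(params.startprob, 1e-300)), log_b)
    return path + 1


def state_indicators(path: np.ndarray, K: int) -> np.ndarray:
    """One-hot ``(T, K)`` expansion of a 1-based state path."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    if path.min() < 1 or path.max() > K:
        raise ValueError(f"path values must lie in 1..{K}")
    ind = np.zeros((path.size, K), dtype=np.int64)
    ind[np.arange(path.size), path - 1] = 1
    return ind


def _as_maps(obj) -> np.ndarray:
    """Channels x K spatial description of a model or map set."""
    if isinstance(obj, HMMParams):
        return obj.means.T
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("map set must be a 2-D channels x K array")
    return arr


def match_states(a, b) -> np.ndarray:
    """Optimal one-to-one state matching between two fits (or map sets).

    Maximizes the summed Pearson correlation between matched spatial maps
    (model state means, or explicit channels x K map columns) by Hungarian
    assignment.  Returns ``perm`` (1-based) such that state ``k`` of ``a``
    corresponds to state ``perm[k-1]`` of ``b``.
    """
    ma, mb = _as_maps(a), _as_maps(b)
    if ma.shape[1] != mb.shape[1]:
        raise ValueError("state counts differ")
    za = (ma - ma.mean(axis=0)) / np.maximum(ma.std(axis=0), 1e-300)
    zb = (mb - mb.mean(axis=0)) / np.maximum(mb.std(axis=0), 1e-300)
    corr = za.T @ zb / ma.shape[0]
    _, cols = linear_sum_assignment(-corr)
    return cols + 1
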