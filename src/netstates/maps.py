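"""State-specific spatial maps via GLM partial correlations.

For each subject, the per-channel envelope is regressed on the full set of
z-scored state indicator time-courses; each coefficient is then the partial
correlation of that state's time-course with the channel envelope given all
other states.  Variants: collapsing a subset of state columns into one
(logical OR) before z-scoring, narrow-band envelopes against the wide-band
state path, time masks restricted to intervals of high state occurrence
rate, ultra-slow occurrence-rate maps, and session-average amplitude maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import occurrence_rate_timecourse

__all__ = [
    "GLMDesign",
    "build_design",
    "partial_correlation_map",
    "band_specific_maps",
    "average_maps",
    "high_rate_mask",
    "ultraslow_rate_map",
    "session_average_amplitude",
]


@dataclass
class GLMDesign:
    """Design matrix for the state GLM.

    ``raw`` holds the (possibly collapsed) indicator columns before
    z-scoring; ``matrix`` the z-scored columns actually used as regressors.
    Keeping both lets time masks be applied before standardization.
    """

    raw: np.ndarray       # (T, K')
    matrix: np.ndarray    # (T, K') z-scored
    labels: list[str]


def _zscore_columns(x: np.ndarray, what: str) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance {what} columns: {bad}")
    return (x - mean) / sd


def build_design(indicators: np.ndarray,
                 collapse: list[int] | None = None) -> GLMDesign:
    """Build the T x K' design from one-hot state indicators.

    ``collapse`` names 1-based state labels whose columns are OR-combined
    into a single regressor (placed at the position of the first named
    state); each column is then z-scored.
    """
    ind = np.asarray(indicators, dtype=float)
    if ind.ndim != 2:
        raise ValueError("indicators must be (T, K)")
    k = ind.shape[1]
    if collapse:
        labels_c = sorted(set(collapse))
        if labels_c != sorted(collapse):
            raise ValueError("collapse labels must be distinct")
        if labels_c[0] < 1 or labels_c[-1] > k:
            raise ValueError(f"collapse labels must lie in 1..{k}")
        idx = [l - 1 for l in labels_c]
        merged = ind[:, idx].max(axis=1)
        keep = [j for j in range(k) if j not in idx[1:]]
        raw = ind[:, keep].copy()
        raw[:, keep.index(idx[0])] = merged
        labels = ["+".join(str(l) for l in labels_c) if j == idx[0] else str(j + 1)
                  for j in keep]
    else:
        raw = ind.copy()
        labels = [str(j + 1) for j in range(k)]
    return GLMDesign(raw=raw, matrix=_zscore_columns(raw, "design"), labels=labels)


def partial_correlation_map(design: GLMDesign, envelopes: np.ndarray,
                            mask: np.ndarray | None = None) -> np.ndarray:
    """Per-channel multiple-regression coefficients on the state design.

    ``envelopes`` is the subject's ``(T, M)`` envelope matrix, time-aligned
    with the design.  With all variables z-scored, each coefficient is the
    partial correlation of the state regressor with the channel given the
    other regressors.  ``mask`` (boolean, length T) restricts the rows
    *before* z-scoring.  Returns ``(M, K')``.
    """
    env = np.asarray(envelopes, dtype=float)
    raw = design.raw
    if env.shape[0] != raw.shape[0]:
        raise ValueError("design and envelope time axes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (raw.shape[0],):
            raise ValueError("mask length must match the time axis")
        raw = raw[mask]
        env = env[mask]
        d = _zscore_columns(raw, "masked design")
    else:
        d = design.matrix
    y = _zscore_columns(env, "envelope")
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        # A complete indicator set sums to 1 at every time point, so the
        # z-scored design always has exactly one redundancy (it spans the
        # implicit intercept).  The minimum-norm solution resolves it
        # symmetrically across states; anything worse is a real error.
        const_sum = np.ptp(raw.sum(axis=1)) < 1e-10
        if not (const_sum and rank == d.shape[1] - 1):
            raise ValueError("rank-deficient design (after masking)")
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    return beta.T  # (M, K')


def band_specific_maps(design: GLMDesign,
                       band_envelopes: dict[str, np.ndarray],
                       mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Maps of the wide-band state design against narrow-band envelopes.

    The states are *not* refit per band; the same design is regressed on
    each band's envelope matrix.
    """
    return {name: partial_correlation_map(design, env, mask=mask)
            for name, env in band_envelopes.items()}


def average_maps(subject_maps: list[np.ndarray],
                 use_absolute: bool = False) -> np.ndarray:
    """Element-wise group mean of subject maps.

    With ``use_absolute`` the mean is over absolute coefficients — used for
    ultra-slow maps, where the modulator phase makes the coefficient sign
    arbitrary across subjects.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    if use_absolute:
        stack = np.abs(stack)
    return stack.mean(axis=0)


def high_rate_mask(path: np.ndarray, K: int, state: int, fs: float,
                   window_s: float = 5.0, quantile: float = 0.75) -> np.ndarray:
    """Time points where a state's occurrence rate is in its top quartile.

    The rate at time t is the state's occupancy in the window centered on t
    (edges use the nearest full window).  Returns a boolean mask of length T
    selecting rate >= the ``quantile`` rate quantile.
    """
    rates = occurrence_rate_timecourse(path, K, fs, window_s=window_s, step=1)
    r = rates[:, state - 1]
    w = int(round(window_s * fs))
    half = (w - 1) // 2
    full = np.concatenate((np.full(half, r[0]), r,
                           np.full(len(path) - len(r) - half, r[-1])))
    thresh = np.quantile(full, quantile)
    return full >= thresh


def ultraslow_rate_map(rates: np.ndarray, slow: np.ndarray) -> np.ndarray:
    """Partial correlations of ultra-slow channel signals with state rates.

    ``rates`` is the ``(Tw, K)`` sliding-window occurrence-rate design,
    ``slow`` the time-aligned ``(Tw, M)`` lowpass (<0.1 Hz) channel signals.
    Returns ``(M, K)``; group averaging should use absolute values.
    """
    rates = np.asarray(rates, dtype=float)
    slow = np.asarray(slow, dtype=float)
    if rates.shape[0] != slow.shape[0]:
        raise ValueError("rate and slow-signal time axes differ")
    design = GLMDesign(raw=rates, matrix=_zscore_columns(rates, "rate"),
                       labels=[str(k + 1) for k in range(rates.shape[1])])
    return partial_correlation_map(design, slow)


def session_average_amplitude(band_envelopes: dict[str, np.ndarray]) -> np.ndarray:
    """Time-mean envelope per channel per band, ``(M, n_bands)``."""
    cols = [np.asarray(env, dtype=float).mean(axis=0)
            for env in band_envelopes.values()]
    return np.column_stack(cols)
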