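"""Temporal summary metrics of decoded state paths.

For a 1-based Viterbi path at sampling rate ``fs``:

* fractional occupancy (FO): fraction of samples spent in each state;
* fractional count (FC): number of visits (contiguous segments) to each
  state as a fraction of the total number of visits across states;
* mean lifetime (LT): average visit duration per state, in milliseconds
  (states never visited are reported as NaN, not zero);
* empirical transition matrix: row-normalized counts of consecutive state
  pairs, with or without the diagonal;
* sliding-window occurrence rate: per-state occupancy within windows of a
  few seconds, the slow time-course used for ultra-slow coupling analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemporalMetrics",
    "fractional_occupancy",
    "fractional_count",
    "mean_lifetime",
    "transition_matrix",
    "occurrence_rate_timecourse",
    "compute_temporal_metrics",
    "metrics_table",
]


def _check_path(path: np.ndarray, K: int) -> np.ndarray:
    path = np.asarray(path, dtype=np.int64).ravel()
    if path.size == 0:
        raise ValueError("empty state path")
    if path.min() < 1 or path.max() > K:
        raise ValueError(f"path values must lie in 1..{K}")
    return path


def _segments(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each visit, visit length in samples).

    Boundary segments count as full visits.
    """
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    return path[starts], ends - starts


def fractional_occupancy(path: np.ndarray, K: int) -> np.ndarray:
    """Fraction of the recording spent in each state; sums to 1."""
    path = _check_path(path, K)
    return np.bincount(path - 1, minlength=K) / path.size


def fractional_count(path: np.ndarray, K: int) -> np.ndarray:
    """Visits to each state as a fraction of all visits; sums to 1."""
    path = _check_path(path, K)
    states, _ = _segments(path)
    return np.bincount(states - 1, minlength=K) / states.size


def mean_lifetime(path: np.ndarray, K: int, fs: float) -> np.ndarray:
    """Mean visit duration per state in ms; NaN for unvisited states."""
    path = _check_path(path, K)
    states, lengths = _segments(path)
    out = np.full(K, np.nan)
    for k in range(K):
        sel = lengths[states == k + 1]
        if sel.size:
            out[k] = sel.mean() * 1000.0 / fs
    return out


def transition_matrix(path: np.ndarray, K: int,
                      mode: str = "with_self") -> np.ndarray:
    """Empirical transition probabilities from consecutive sample pairs.

    ``with_self`` keeps the diagonal; ``exclude_self`` zeroes it before
    renormalizing (transitions to any *other* state).  Rows of states never
    occupied at a "from" position are NaN.
    """
    path = _check_path(path, K)
    if path.size < 2:
        raise ValueError("path must have at least 2 samples")
    if mode not in ("with_self", "exclude_self"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.zeros((K, K))
    np.add.at(counts, (path[:-1] - 1, path[1:] - 1), 1.0)
    if mode == "exclude_self":
        np.fill_diagonal(counts, 0.0)
    rowsum = counts.sum(axis=1)
    out = np.full((K, K), np.nan)
    visited = rowsum > 0
    out[visited] = counts[visited] / rowsum[visited, None]
    return out


def occurrence_rate_timecourse(path: np.ndarray, K: int, fs: float,
                               window_s: float = 5.0,
                               step: int = 1) -> np.ndarray:
    """Per-state occupancy within sliding windows.

    Window length is ``window_s * fs`` samples (100 at 20 Hz for the default
    5 s, half a cycle of a 0.1 Hz oscillation); windows start every ``step``
    samples, giving ``floor((T - w)/step) + 1`` rows.
    """
    path = _check_path(path, K)
    w = int(round(window_s * fs))
    if path.size < w:
        raise ValueError(f"path ({path.size}) shorter than window ({w})")
    ind = np.zeros((path.size, K))
    ind[np.arange(path.size), path - 1] = 1.0
    csum = np.concatenate((np.zeros((1, K)), np.cumsum(ind, axis=0)))
    starts = np.arange(0, path.size - w + 1, step)
    return (csum[starts + w] - csum[starts]) / w


@dataclass
class TemporalMetrics:
    """Per-subject summary of one decoded path."""

    FO: np.ndarray
    FC: np.ndarray
    LT_ms: np.ndarray
    transmat: np.ndarray
    subject: str = ""
    group: str = ""


def compute_temporal_metrics(path: np.ndarray, K: int, fs: float,
                             subject: str = "", group: str = "",
                             mode: str = "with_self") -> TemporalMetrics:
    return TemporalMetrics(
        FO=fractional_occupancy(path, K),
        FC=fractional_count(path, K),
        LT_ms=mean_lifetime(path, K, fs),
        transmat=transition_matrix(path, K, mode=mode),
        subject=subject,
        group=group,
    )


def metrics_table(metrics: list[TemporalMetrics]) -> pd.DataFrame:
    """Long-format table: one row per (subject, state)."""
    rows = []
    for m in metrics:
        for k in range(m.FO.size):
            rows.append({
                "subject": m.subject,
                "group": m.group,
                "state": k + 1,
                "FO": m.FO[k],
                "FC": m.FC[k],
                "LT_ms": m.LT_ms[k],
            })
    return pd.DataFrame(rows)
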