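"""Amplitude-envelope preprocessing for band-limited oscillatory signals.

The preprocessing chain mirrors the standard envelope functional-connectivity
recipe: zero-phase band filtering, symmetric orthogonalization of the channel
time-courses to remove zero-lag signal leakage, Hilbert envelopes, block-mean
downsampling to the analysis rate (20 Hz by default), and per-subject
normalization before temporal concatenation across subjects.

Array conventions
-----------------
Raw signals are ``(channels, time)``; envelope matrices are ``(time,
channels)``.  Filtering and envelope extraction operate along ``axis=-1`` so
they apply directly to raw matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

__all__ = [
    "BandSpec",
    "BANDS",
    "bandpass",
    "lowpass_ultraslow",
    "extract_roi_timecourse",
    "symmetric_orthogonalize",
    "hilbert_envelope",
    "downsample_envelope",
    "normalize_concatenate",
    "raw_to_envelope",
]

#: Butterworth order per pass (applied forward-backward, so the effective
#: attenuation is doubled and the phase response is zero).
FILTER_ORDER = 5


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: bandpass ``(low, high)`` or lowpass at ``high``."""

    name: str
    low: float | None
    high: float
    btype: str = "bandpass"  # "bandpass" | "lowpass"

    def __post_init__(self):
        if self.btype == "bandpass":
            if self.low is None or not (0 < self.low < self.high):
                raise ValueError(f"invalid bandpass edges ({self.low}, {self.high})")
        elif self.btype == "lowpass":
            if self.high <= 0:
                raise ValueError("lowpass cutoff must be positive")
        else:
            raise ValueError(f"unknown btype {self.btype!r}")


#: Band presets: wide analysis band, the three narrow bands, and the
#: ultra-slow (<0.1 Hz) potential band.
BANDS: dict[str, BandSpec] = {
    "wide": BandSpec("wide", 4.0, 30.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 15.0, 30.0),
    "ultraslow": BandSpec("ultraslow", None, 0.1, btype="lowpass"),
}


def _sos(band: BandSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band edge {band.high} Hz is at/above Nyquist ({nyq} Hz)")
    if band.btype == "bandpass":
        return signal.butter(FILTER_ORDER, [band.low, band.high], btype="bandpass",
                             fs=fs, output="sos")
    return signal.butter(FILTER_ORDER, band.high, btype="lowpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: BandSpec, fs: float, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth filtering of ``x`` into ``band``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return signal.sosfiltfilt(_sos(band, fs), x, axis=axis)


def lowpass_ultraslow(x: np.ndarray, fs: float, cutoff: float = 0.1,
                      axis: int = -1) -> np.ndarray:
    """Zero-phase lowpass at ``cutoff`` Hz (default 0.1 Hz, the ultra-slow band)."""
    band = BandSpec("ultraslow", None, cutoff, btype="lowpass")
    return bandpass(x, band, fs, axis=axis)


def extract_roi_timecourse(voxels: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Reduce a ``(time, V)`` voxel block to one representative time-course.

    Voxel columns are weighted by the spatial-map strength, centered, and the
    first principal component is extracted.  The spatial loading is sign-fixed
    so its largest-magnitude element is positive and rescaled to unit peak;
    the returned time-course is scaled accordingly, so its amplitude reflects
    the signal at the map peak.
    """
    voxels = np.asarray(voxels, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    if voxels.ndim != 2:
        raise ValueError("voxels must be (time, V)")
    if voxels.shape[1] != weights.size:
        raise ValueError("weights length must match voxel count")
    xw = voxels * weights
    xw = xw - xw.mean(axis=0)
    if not np.any(xw):
        raise ValueError("all-zero voxel block after weighting/centering")
    u, s, vt = np.linalg.svd(xw, full_matrices=False)
    w = vt[0]
    peak = np.argmax(np.abs(w))
    if w[peak] < 0:
        w, u0 = -w, -u[:, 0]
    else:
        u0 = u[:, 0]
    # time-course such that xw ≈ tc @ (w / w[peak]).T
    return u0 * s[0] * w[peak]


def symmetric_orthogonalize(x: np.ndarray, tol: float = 1e-10,
                            max_iter: int = 1000) -> np.ndarray:
    """Closest set of mutually orthogonal columns to ``x`` (least squares).

    Solves ``min ||X - O diag(d)||_F`` over orthonormal ``O`` and magnitudes
    ``d`` by alternating the orthogonal-Procrustes solution (SVD) with the
    per-column magnitude update.  Unlike sequential Gram-Schmidt the result
    does not depend on column order, and it is the global least-squares
    correction among orthogonal column sets.

    Raises on rank-deficient input (naming the dependent columns) and on
    non-convergence (reporting the residual objective change).
    """
    x = np.asarray(x, dtype=float)
    t, m = x.shape
    if t < m:
        raise ValueError(f"need at least as many rows as columns (got {t} x {m})")
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[-1] <= max(t, m) * np.finfo(float).eps * sv[0]:
        # name offending columns via pivoted QR: small trailing R diagonals
        _, r, piv = linalg.qr(x, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(piv[diag <= diag[0] * 1e-10])
        raise ValueError(f"rank-deficient input; dependent columns: {bad}")

    d = np.linalg.norm(x, axis=0)
    prev = np.inf
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x * d, full_matrices=False)
        o = u @ vt
        d = np.einsum("tm,tm->m", x, o)
        obj = np.linalg.norm(x - o * d, ord="fro") ** 2
        if prev - obj <= tol * max(obj, 1.0):
            return o * d
        prev = obj
    raise RuntimeError(
        f"symmetric orthogonalization did not converge in {max_iter} iterations "
        f"(last objective change {prev - obj:.3e})"
    )


def hilbert_envelope(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic (Hilbert) signal."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    from scipy.fft import next_fast_len

    n = x.shape[axis]
    analytic = signal.hilbert(x, N=next_fast_len(n), axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, n)
    return np.abs(analytic[tuple(sl)])


def downsample_envelope(env: np.ndarray, fs: float, target_fs: float = 20.0) -> np.ndarray:
    """Block-mean downsampling of a ``(time, channels)`` envelope.

    Averaging consecutive ``fs/target_fs`` samples anti-aliases the envelope;
    the ratio must be an integer.
    """
    env = np.asarray(env, dtype=float)
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs/target_fs must be an integer, got {ratio}")
    r = int(round(ratio))
    t_out = env.shape[0] // r
    return env[: t_out * r].reshape(t_out, r, -1).mean(axis=1)


def normalize_concatenate(envelopes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Demean and scale per subject, then stack subjects in time.

    Each subject's channels are demeaned and the whole subject matrix is
    divided by its global standard deviation over all entries, so subjects
    contribute on a common scale.  Returns the concatenated ``(T, M)`` matrix
    and the cumulative subject end indices (the boundary after subject ``i``
    is ``boundaries[i]``).
    """
    if not envelopes:
        raise ValueError("no subjects to concatenate")
    m = envelopes[0].shape[1]
    out = []
    for i, env in enumerate(envelopes):
        env = np.asarray(env, dtype=float)
        if env.shape[1] != m:
            raise ValueError(
                f"subject {i} has {env.shape[1]} channels, expected {m}"
            )
        centered = env - env.mean(axis=0)
        sd = centered.std()
        if sd == 0:
            raise ValueError(f"subject {i} has zero global variance")
        out.append(centered / sd)
    boundaries = np.cumsum([e.shape[0] for e in out])
    return np.vstack(out), boundaries


def raw_to_envelope(
    raw: np.ndarray,
    fs: float,
    band: BandSpec | str = "wide",
    target_fs: float = 20.0,
    orthogonalize: bool = True,
    trim_s: float = 1.0,
) -> np.ndarray:
    """Full per-subject chain: filter -> (leakage correction) -> envelope ->
    downsample -> edge trim.

    ``raw`` is ``(channels, time)``; the result is ``(time, channels)`` at
    ``target_fs``.  ``trim_s`` seconds are dropped from each end to suppress
    filter/Hilbert edge transients.  Leakage correction (symmetric
    orthogonalization) is applied to the band-limited time-courses before the
    envelope, and can be disabled for channel-level map envelopes.
    """
    if isinstance(band, str):
        band = BANDS[band]
    filt = bandpass(raw, band, fs, axis=-1)
    if orthogonalize:
        filt = symmetric_orthogonalize(filt.T).T
    env = hilbert_envelope(filt, axis=-1).T  # -> (time, channels)
    env = downsample_envelope(env, fs, target_fs)
    trim = int(round(trim_s * target_fs))
    if trim > 0:
        if env.shape[0] <= 2 * trim:
            raise ValueError("recording shorter than twice the edge trim")
        env = env[trim:-trim]
    return env
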