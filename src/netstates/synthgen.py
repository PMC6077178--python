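"""Ground-truthed synthetic cohorts for the network-state pipeline.

The generator plants exactly the statistical structure the analysis assumes:
a latent K-state Markov chain (one per subject, simulated at the 20 Hz
envelope rate and sample-held to the 200 Hz raw rate) modulates the
instantaneous amplitude of band-limited (4-30 Hz) Gaussian carriers through
state-specific channel topographies.  Optional ingredients: zero-lag leakage
mixing across channels, an ultra-slow (<0.1 Hz) modulator that both biases
the entry probability of one state and adds a slow potential to that state's
channels, and stationary surrogate datasets matched to a reference in
per-channel spectra and zero-lag cross-correlation.

Two cohort presets encode the study conditions: ``ch_default`` (healthy-
control-like) and ``ad_default`` (Alzheimer-like), differing in the
occupancy and dwell time of the DMN-like and DAN-like states and in the
DMN-like modulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import BANDS, bandpass

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_topographies",
    "build_transition_matrix",
    "simulate_state_sequence",
    "simulate_cohort",
    "simulate_ultraslow_modulation",
    "simulate_surrogate",
    "ch_default",
    "ad_default",
]

#: Indices (1-based state labels) of the two salient planted states.
DMN_STATE = 1
DAN_STATE = 6


@dataclass
class SynthConfig:
    """Parameters of a synthetic cohort.

    ``occupancy`` is the target stationary distribution of the latent chain
    (sums to 1); ``self_transition`` the per-state self-transition
    probability at the envelope rate, so the planted mean dwell of state k is
    ``1/(fs_env*(1-p_k))`` seconds.  ``depth`` scales the amplitude boost
    ``1 + depth*depth_scale_k*topography[k, ch]`` applied while state k is
    active.
    """

    n_subjects: int = 10
    duration_s: float = 540.0
    fs_raw: float = 200.0
    fs_env: float = 20.0
    n_channels: int = 38
    K: int = 10
    occupancy: np.ndarray | None = None       # (K,)
    self_transition: np.ndarray | None = None  # (K,)
    topographies: np.ndarray | None = None     # (K, M) nonnegative
    depth: float = 1.0
    depth_scale: np.ndarray | None = None      # (K,)
    leakage: np.ndarray | None = None          # (M, M) mixing, default identity
    ultraslow_freq: float = 0.05
    ultraslow_gain: float = 0.0
    ultraslow_state: int = DMN_STATE           # 1-based coupled state
    ultraslow_amp: float = 0.5
    noise_sd: float = 0.2
    group: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("n_subjects and n_channels must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        n_raw = self.duration_s * self.fs_raw
        if abs(n_raw - round(n_raw)) > 1e-9:
            raise ValueError("duration_s * fs_raw must be an integer sample count")
        ratio = self.fs_raw / self.fs_env
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fs_raw must be an integer multiple of fs_env")
        if self.occupancy is None:
            self.occupancy = np.full(self.K, 1.0 / self.K)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (self.K,) or abs(self.occupancy.sum() - 1) > 1e-8:
            raise ValueError("occupancy must be a length-K distribution summing to 1")
        if self.self_transition is None:
            self.self_transition = np.full(self.K, 2.0 / 3.0)
        self.self_transition = np.asarray(self.self_transition, dtype=float)
        if np.any(self.self_transition < 0) or np.any(self.self_transition >= 1):
            raise ValueError("self-transition probabilities must lie in [0, 1)")
        if self.topographies is None:
            self.topographies = default_topographies(self.K, self.n_channels)
        self.topographies = np.asarray(self.topographies, dtype=float)
        if self.topographies.shape != (self.K, self.n_channels):
            raise ValueError("topographies must be (K, n_channels)")
        if np.any(self.topographies < 0):
            raise ValueError("topography weights must be nonnegative")
        if self.depth_scale is None:
            self.depth_scale = np.ones(self.K)
        self.depth_scale = np.asarray(self.depth_scale, dtype=float)
        if self.ultraslow_freq >= 0.1:
            raise ValueError("ultraslow_freq must be below 0.1 Hz")
        if not 1 <= self.ultraslow_state <= self.K:
            raise ValueError("ultraslow_state must be a 1-based state label")

    @property
    def t_env(self) -> int:
        return int(round(self.duration_s * self.fs_env))

    @property
    def t_raw(self) -> int:
        return int(round(self.duration_s * self.fs_raw))


@dataclass
class GroundTruth:
    """Planted structure returned alongside a simulated cohort."""

    paths: list[np.ndarray]            # per subject, 1..K at fs_env
    topographies: np.ndarray           # (K, M)
    transition_matrix: np.ndarray      # (K, K) used by the group
    occupancy: np.ndarray              # (K,) planted stationary distribution
    groups: list[str]
    fs_env: float
    modulators: list[np.ndarray] = field(default_factory=list)


def default_topographies(K: int, M: int) -> np.ndarray:
    """Disjoint channel blocks, one per state, with unit weight.

    Channels are split into K contiguous blocks (sizes differing by at most
    one); state k modulates exactly its own block.  Blocks double as the
    spatial neighbourhoods for cluster-based statistics.
    """
    if M < K:
        raise ValueError("need at least one channel per state")
    sizes = np.full(K, M // K)
    sizes[: M % K] += 1
    topo = np.zeros((K, M))
    start = 0
    for k, s in enumerate(sizes):
        topo[k, start : start + s] = 1.0
        start += s
    return topo


def build_transition_matrix(occupancy: np.ndarray, self_transition: np.ndarray,
                            max_iter: int = 200, tol: float = 1e-13) -> np.ndarray:
    """Row-stochastic matrix with exact stationary ``occupancy`` and exact
    per-state self-transition probabilities.

    Uses the reversible family ``A_jk = c_j pi_k c_k / C`` (j != k), which
    satisfies detailed balance for any positive rates ``c``; the rates are
    solved by fixed-point iteration so each diagonal hits its target.
    """
    pi = np.asarray(occupancy, dtype=float)
    p = np.asarray(self_transition, dtype=float)
    K = pi.size
    if K == 1:
        return np.ones((1, 1))
    exit_rate = 1.0 - p
    c = exit_rate.copy()
    for _ in range(max_iter):
        r = pi * c
        cap = r.sum()
        # diagonal: 1 - c_j (C - r_j)/C  -> match p_j
        c_new = exit_rate * cap / (cap - r)
        if np.max(np.abs(c_new - c)) < tol:
            c = c_new
            break
        c = c_new
    r = pi * c
    cap = r.sum()
    a = np.outer(c, r) / cap
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(a, 1.0 - a.sum(axis=1))
    if np.any(np.diag(a) < 0):
        raise ValueError("infeasible occupancy/self-transition combination")
    return a


def _check_stochastic(a: np.ndarray, pi: np.ndarray) -> None:
    a = np.asarray(a, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(a < 0) or np.max(np.abs(a.sum(axis=1) - 1)) > 1e-12:
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    if np.any(pi < 0) or abs(pi.sum() - 1) > 1e-12:
        raise ValueError("initial distribution must sum to 1")


def simulate_state_sequence(a: np.ndarray, pi: np.ndarray, t: int,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Length-``t`` realization of a Markov chain; states labeled 1..K."""
    _check_stochastic(a, pi)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.asarray(a, dtype=float)
    cum = np.cumsum(a, axis=1)
    u = rng.random(t)
    path = np.empty(t, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    path[0] = s
    for i in range(1, t):
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        if s >= a.shape[0]:  # guard against cumsum rounding
            s = a.shape[0] - 1
        path[i] = s
    return path + 1


def _modulated_sequence(schedule: np.ndarray, pi: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Markov path under a time-varying transition schedule (T, K, K)."""
    t = schedule.shape[0]
    u = rng.random(t)
    path = np.empty(t, dtype=np.int64)
    s = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    path[0] = s
    for i in range(1, t):
        s = int(np.searchsorted(np.cumsum(schedule[i, s]), u[i], side="right"))
        if s >= schedule.shape[1]:
            s = schedule.shape[1] - 1
        path[i] = s
    return path + 1


def _subject_modulator(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude sinusoid at the ultra-slow frequency, random phase."""
    t = np.arange(cfg.t_env) / cfg.fs_env
    phase = rng.uniform(0, 2 * np.pi)
    return np.sin(2 * np.pi * cfg.ultraslow_freq * t + phase)


def simulate_ultraslow_modulation(
    cfg: SynthConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject ultra-slow modulators and transition schedules.

    The probability of *entering* the coupled state is scaled by
    ``1 + gain * modulator_t`` (rows renormalized); the same modulator is
    later added as a slow potential to the coupled state's channels.
    Returns ``(modulators, schedules)`` with each schedule ``(T, K, K)``.
    """
    if abs(cfg.ultraslow_gain) > 1:
        raise ValueError("ultraslow gain > 1 would produce negative probabilities")
    a = build_transition_matrix(cfg.occupancy, cfg.self_transition)
    j = cfg.ultraslow_state - 1
    ss = np.random.SeedSequence([cfg.seed, 0x5107])
    rngs = [np.random.default_rng(s) for s in ss.spawn(cfg.n_subjects)]
    modulators, schedules = [], []
    for rng in rngs:
        mod = _subject_modulator(cfg, rng)
        sched = np.broadcast_to(a, (cfg.t_env, cfg.K, cfg.K)).copy()
        scale = 1.0 + cfg.ultraslow_gain * mod
        sched[:, :, j] *= scale[:, None]
        sched[:, j, j] = a[j, j]  # self-persistence unchanged; only entries biased
        sched /= sched.sum(axis=2, keepdims=True)
        modulators.append(mod)
        schedules.append(sched)
    return modulators, schedules


def _band_carrier(shape: tuple[int, int], fs: float, rng: np.random.Generator,
                  band=BANDS["wide"]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, ``(channels, time)``."""
    white = rng.standard_normal(shape)
    carrier = bandpass(white, band, fs, axis=-1)
    return carrier / carrier.std(axis=-1, keepdims=True)


def simulate_cohort(cfg: SynthConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Simulate one cohort; returns raw ``(channels, time)`` matrices and the
    planted ground truth (paths at the envelope rate).

    Per subject: the latent path is simulated at ``fs_env``, sample-held to
    ``fs_raw``, and each channel's band-limited carrier is multiplied by
    ``1 + depth * depth_scale_k * topography[k, ch]`` while state k is
    active.  Leakage mixing, the ultra-slow potential, and white measurement
    noise are applied afterwards.
    """
    a = build_transition_matrix(cfg.occupancy, cfg.self_transition)
    ratio = int(round(cfg.fs_raw / cfg.fs_env))
    ss = np.random.SeedSequence([cfg.seed, 0xC04])
    child = ss.spawn(cfg.n_subjects)
    use_mod = cfg.ultraslow_gain != 0.0
    if use_mod:
        modulators, schedules = simulate_ultraslow_modulation(cfg)
    raws, paths, mods = [], [], []
    j = cfg.ultraslow_state - 1
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(child[i])
        if use_mod:
            path = _modulated_sequence(schedules[i], cfg.occupancy, rng)
            mod = modulators[i]
        else:
            path = simulate_state_sequence(a, cfg.occupancy, cfg.t_env, rng)
            mod = None
        carrier = _band_carrier((cfg.n_channels, cfg.t_raw), cfg.fs_raw, rng)
        gain_env = 1.0 + cfg.depth * (cfg.depth_scale[:, None]
                                      * cfg.topographies)[path - 1]  # (T_env, M)
        gain_raw = np.repeat(gain_env, ratio, axis=0).T  # (M, T_raw)
        x = carrier * gain_raw
        if cfg.leakage is not None:
            x = np.asarray(cfg.leakage, dtype=float) @ x
        if use_mod:
            slow = np.repeat(mod, ratio) * cfg.ultraslow_amp
            x[cfg.topographies[j] > 0] += slow
            mods.append(mod)
        if cfg.noise_sd > 0:
            x = x + cfg.noise_sd * rng.standard_normal(x.shape)
        raws.append(x)
        paths.append(path)
    gt = GroundTruth(
        paths=paths,
        topographies=cfg.topographies.copy(),
        transition_matrix=a,
        occupancy=cfg.occupancy.copy(),
        groups=[cfg.group] * cfg.n_subjects,
        fs_env=cfg.fs_env,
        modulators=mods,
    )
    return raws, gt


def simulate_surrogate(reference: np.ndarray, n_datasets: int,
                       seed: int = 0) -> list[np.ndarray]:
    """Stationary Gaussian surrogates matched to ``reference`` in per-channel
    spectra and zero-lag cross-correlation.

    ``reference`` is ``(time, channels)``.  White noise is colored channel by
    channel with the reference amplitude spectrum, then the reference
    zero-lag covariance is imposed through symmetric matrix square roots.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] < 2:
        raise ValueError("reference must be (time, channels) with >= 2 channels")
    t, m = ref.shape
    if t <= m:
        raise ValueError("reference must have more samples than channels")
    refc = ref - ref.mean(axis=0)
    cov = refc.T @ refc / t
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-1] <= 0 or eigval[0] <= 1e-12 * eigval[-1]:
        rank = int(np.sum(eigval > 1e-12 * max(eigval[-1], 1e-300)))
        raise ValueError(f"singular reference covariance (rank {rank} of {m})")
    cov_sqrt = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T
    # per-channel coloring filter: smoothed amplitude spectrum (the raw
    # periodogram is itself a noisy estimate; smoothing keeps the surrogate
    # spectrum close to the reference's underlying one)
    from scipy.ndimage import uniform_filter1d

    power = np.abs(np.fft.rfft(refc, axis=0)) ** 2
    width = max(5, power.shape[0] // 50)
    amp = np.sqrt(uniform_filter1d(power, size=width, axis=0, mode="nearest"))
    ss = np.random.SeedSequence([seed, 0x5A6])
    out = []
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        white = rng.standard_normal((t, m))
        colored = np.fft.irfft(np.fft.rfft(white, axis=0) * amp, n=t, axis=0)
        colored -= colored.mean(axis=0)
        ccov = colored.T @ colored / t
        w, v = np.linalg.eigh(ccov)
        inv_sqrt = v @ np.diag(1.0 / np.sqrt(np.maximum(w, 1e-300))) @ v.T
        out.append(colored @ inv_sqrt @ cov_sqrt)
    return out


def _preset_base(n_subjects: int, duration_s: float, seed: int) -> dict:
    return dict(n_subjects=n_subjects, duration_s=duration_s, seed=seed,
                fs_raw=200.0, fs_env=20.0, n_channels=38, K=10)


def _dwell_to_self(fs_env: float, dwell_ms: np.ndarray) -> np.ndarray:
    return 1.0 - 1000.0 / (fs_env * np.asarray(dwell_ms, dtype=float))


def ch_default(n_subjects: int = 10, duration_s: float = 540.0,
               seed: int = 0) -> SynthConfig:
    """Healthy-control-like cohort preset.

    DMN-like (state 1) occupies 6% with 250 ms dwells, DAN-like (state 6)
    14% with 225 ms dwells; the eight remaining states share the rest
    equally with 150 ms dwells.
    """
    occ = np.full(10, 0.10)
    occ[DMN_STATE - 1] = 0.06
    occ[DAN_STATE - 1] = 0.14
    dwell = np.full(10, 150.0)
    dwell[DMN_STATE - 1] = 250.0
    dwell[DAN_STATE - 1] = 225.0
    return SynthConfig(occupancy=occ, self_transition=_dwell_to_self(20.0, dwell),
                       group="CH", **_preset_base(n_subjects, duration_s, seed))


def ad_default(n_subjects: int = 10, duration_s: float = 540.0,
               seed: int = 0) -> SynthConfig:
    """Alzheimer-like cohort preset.

    DMN-like and DAN-like occupancies halved relative to the control preset
    (3% and 7%), both with 150 ms dwells, and the DMN-like modulation depth
    reduced (scale 0.8); the remaining states absorb the freed occupancy.
    """
    occ = np.full(10, 0.1125)
    occ[DMN_STATE - 1] = 0.03
    occ[DAN_STATE - 1] = 0.07
    dwell = np.full(10, 150.0)
    scale = np.ones(10)
    scale[DMN_STATE - 1] = 0.8
    return SynthConfig(occupancy=occ, self_transition=_dwell_to_self(20.0, dwell),
                       depth_scale=scale, group="AD",
                       **_preset_base(n_subjects, duration_s, seed))
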