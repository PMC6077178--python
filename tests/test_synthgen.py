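"""Tests of the synthetic-cohort generator: latent-chain statistics,
ground-truth alignment, ultra-slow coupling, and surrogate matching."""

import numpy as np
import pytest

from netstates import envelope as env
from netstates import synthgen as sg
from netstates.metrics import fractional_occupancy, mean_lifetime


class TestStateSequence:
    def test_absorbing_chain_stays_in_state_one(self):
        a = np.eye(3)
        path = sg.simulate_state_sequence(a, [1.0, 0, 0], 50, seed=0)
        assert np.all(path == 1)

    def test_symmetric_two_state_occupancy_is_half(self):
        a = np.array([[0.8, 0.2], [0.2, 0.8]])
        path = sg.simulate_state_sequence(a, [0.5, 0.5], 100_000, seed=1)
        fo = fractional_occupancy(path, 2)
        assert np.allclose(fo, 0.5, atol=0.01)

    def test_geometric_dwell_mean_matches_self_transition(self):
        a = np.array([[0.8, 0.2], [0.2, 0.8]])
        path = sg.simulate_state_sequence(a, [0.5, 0.5], 200_000, seed=2)
        lt = mean_lifetime(path, 2, fs=1.0)  # ms at fs=1 -> samples x 1000
        assert np.allclose(lt / 1000.0, 5.0, rtol=0.03)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            sg.simulate_state_sequence(np.array([[0.5, 0.4], [0.2, 0.8]]),
                                       [0.5, 0.5], 10, seed=0)

    def test_reproducible_under_fixed_seed(self):
        a = np.array([[0.9, 0.1], [0.3, 0.7]])
        p1 = sg.simulate_state_sequence(a, [0.5, 0.5], 1000, seed=42)
        p2 = sg.simulate_state_sequence(a, [0.5, 0.5], 1000, seed=42)
        assert np.array_equal(p1, p2)


class TestTransitionMatrixConstruction:
    def test_targets_hit_exactly(self):
        occ = np.array([0.06, 0.14, 0.4, 0.4])
        p_self = np.array([0.8, 2 / 3, 0.5, 0.6])
        a = sg.build_transition_matrix(occ, p_self)
        assert np.allclose(a.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(np.diag(a), p_self, atol=1e-10)
        assert np.allclose(occ @ a, occ, atol=1e-12)  # stationary


class TestCohort:
    def test_ground_truth_path_length_matches_envelope_rate(self):
        cfg = sg.SynthConfig(n_subjects=1, duration_s=180.0, n_channels=8,
                             K=4, seed=0)
        _, gt = sg.simulate_cohort(cfg)
        assert gt.paths[0].size == 180 * 20

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            sg.SynthConfig(n_subjects=1, duration_s=-5.0, n_channels=8, K=4)

    def test_determinism_bitwise(self):
        cfg = dict(n_subjects=2, duration_s=30.0, n_channels=6, K=3, seed=5)
        r1, g1 = sg.simulate_cohort(sg.SynthConfig(**cfg))
        r2, g2 = sg.simulate_cohort(sg.SynthConfig(**cfg))
        assert all(np.array_equal(a, b) for a, b in zip(r1, r2))
        assert all(np.array_equal(a, b) for a, b in zip(g1.paths, g2.paths))

    def test_planted_state_raises_envelope_on_its_channels(self, small_cohort):
        """During visits to a planted state, the envelope of that state's
        channels sits above its out-of-state level."""
        cfg, raws, gt = small_cohort
        raw, path = raws[0], gt.paths[0]
        e = env.hilbert_envelope(env.bandpass(raw, env.BANDS["wide"], cfg.fs_raw))
        e20 = env.downsample_envelope(e.T, cfg.fs_raw, cfg.fs_env)
        k = 2  # state 2 has plenty of visits
        own = cfg.topographies[k - 1] > 0
        inside = e20[path == k][:, own].mean()
        outside = e20[path != k][:, own].mean()
        assert inside > 1.3 * outside

    def test_zero_depth_leaves_no_topographic_signature(self):
        cfg = sg.SynthConfig(n_subjects=1, duration_s=60.0, n_channels=8,
                             K=4, depth=0.0, seed=9)
        raws, gt = sg.simulate_cohort(cfg)
        e = env.hilbert_envelope(env.bandpass(raws[0], env.BANDS["wide"], cfg.fs_raw))
        e20 = env.downsample_envelope(e.T, cfg.fs_raw, cfg.fs_env)
        path = gt.paths[0]
        own = cfg.topographies[0] > 0
        inside = e20[path == 1][:, own].mean()
        outside = e20[path != 1][:, own].mean()
        assert abs(inside / outside - 1) < 0.05


class TestUltraslow:
    def test_modulator_period(self):
        cfg = sg.SynthConfig(n_subjects=1, duration_s=60.0, n_channels=6,
                             K=3, ultraslow_freq=0.05, ultraslow_gain=0.5,
                             seed=3)
        mods, scheds = sg.simulate_ultraslow_modulation(cfg)
        mod = mods[0]
        # 0.05 Hz -> 20 s period -> 3 cycles in 60 s
        spec = np.abs(np.fft.rfft(mod))
        assert np.argmax(spec[1:]) + 1 == 3
        assert np.allclose(scheds[0].sum(axis=2), 1, atol=1e-12)

    def test_gain_couples_rate_to_modulator(self):
        from netstates.metrics import occurrence_rate_timecourse

        cfg = sg.SynthConfig(n_subjects=1, duration_s=540.0, n_channels=6,
                             K=3, occupancy=[0.2, 0.4, 0.4],
                             self_transition=[0.8, 0.7, 0.7],
                             ultraslow_freq=0.05, ultraslow_gain=0.9,
                             ultraslow_state=1, seed=4)
        raws, gt = sg.simulate_cohort(cfg)
        rate = occurrence_rate_timecourse(gt.paths[0], 3, cfg.fs_env)[:, 0]
        mod = gt.modulators[0][: rate.size]
        r = np.corrcoef(rate, mod)[0, 1]
        assert r > 0.5

    def test_zero_gain_uncoupled(self):
        from netstates.metrics import occurrence_rate_timecourse

        cfg = sg.SynthConfig(n_subjects=1, duration_s=540.0, n_channels=6,
                             K=3, ultraslow_gain=0.0, seed=4)
        raws, gt = sg.simulate_cohort(cfg)
        mods, _ = sg.simulate_ultraslow_modulation(cfg)
        rate = occurrence_rate_timecourse(gt.paths[0], 3, cfg.fs_env)[:, 0]
        r = np.corrcoef(rate, mods[0][: rate.size])[0, 1]
        assert abs(r) < 0.1

    def test_excessive_gain_rejected(self):
        with pytest.raises(ValueError):
            cfg = sg.SynthConfig(n_subjects=1, duration_s=60.0, n_channels=6,
                                 K=3, ultraslow_gain=1.5, seed=0)
            sg.simulate_ultraslow_modulation(cfg)


class TestSurrogate:
    def test_count_and_distinctness(self):
        rng = np.random.default_rng(0)
        ref = rng.standard_normal((2000, 3))
        surr = sg.simulate_surrogate(ref, 5, seed=1)
        assert len(surr) == 5
        assert not np.allclose(surr[0], surr[1])

    def test_correlation_matched(self):
        rng = np.random.default_rng(2)
        mix = np.array([[1.0, 0.0, 0.0], [0.7, 0.7, 0.0], [0.3, 0.3, 0.9]])
        ref = rng.standard_normal((100_000, 3)) @ mix.T
        surr = sg.simulate_surrogate(ref, 1, seed=3)[0]
        c_ref = np.corrcoef(ref.T)
        c_surr = np.corrcoef(surr.T)
        assert np.max(np.abs(c_ref - c_surr)) < 0.05

    def test_spectrum_matched(self):
        from scipy import signal as sps

        rng = np.random.default_rng(4)
        white = rng.standard_normal((20000, 2))
        ref = sps.sosfiltfilt(sps.butter(4, [0.05, 0.2], btype="bandpass",
                                         output="sos"), white, axis=0)
        surr = sg.simulate_surrogate(ref, 1, seed=5)[0]
        f, p_ref = sps.welch(ref[:, 0], nperseg=1024)
        _, p_surr = sps.welch(surr[:, 0], nperseg=1024)
        band = (f > 0.02) & (f < 0.12)
        ratio = p_surr[band] / p_ref[band]
        assert np.median(np.abs(np.log(ratio))) < 0.35

    def test_white_reference_gives_flat_surrogate(self):
        from scipy import signal as sps

        rng = np.random.default_rng(6)
        ref = rng.standard_normal((40000, 3))
        surr = sg.simulate_surrogate(ref, 1, seed=7)[0]
        f, p = sps.welch(surr[:, 0], fs=200.0, nperseg=1024)
        edges = np.linspace(4.0, 30.0, 6)
        band_power = [p[(f >= lo) & (f < hi)].mean()
                      for lo, hi in zip(edges[:-1], edges[1:])]
        assert max(band_power) / min(band_power) < 1.5

    def test_singular_reference_reports_rank(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((1000, 2))
        ref = np.column_stack([base, base[:, 0]])  # rank 2 of 3
        with pytest.raises(ValueError, match="rank"):
            sg.simulate_surrogate(ref, 1, seed=0)
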