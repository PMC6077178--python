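"""Tests of the GLM partial-correlation state maps and their variants."""

import numpy as np
import pytest

from netstates import maps
from netstates import synthgen as sg
from netstates.hmm import state_indicators


def _random_path(K, T, seed):
    return np.random.default_rng(seed).integers(1, K + 1, size=T)


class TestBuildDesign:
    def test_full_design_shape_and_moments(self):
        ind = state_indicators(_random_path(10, 2000, 0), 10)
        d = maps.build_design(ind)
        assert d.matrix.shape == (2000, 10)
        assert np.allclose(d.matrix.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(d.matrix.std(axis=0), 1.0, atol=1e-8)

    def test_collapse_four_into_one(self):
        ind = state_indicators(_random_path(10, 2000, 1), 10)
        d = maps.build_design(ind, collapse=[1, 4, 5, 7])
        assert d.matrix.shape == (2000, 7)
        assert "1+4+5+7" in d.labels

    def test_collapsed_column_is_logical_or(self):
        ind = state_indicators(np.array([1, 4, 2, 5, 3]), 5)
        d = maps.build_design(ind, collapse=[1, 4])
        merged_raw = d.raw[:, d.labels.index("1+4")]
        assert np.array_equal(merged_raw, [1, 1, 0, 0, 0])

    def test_duplicate_collapse_labels_rejected(self):
        ind = state_indicators(_random_path(5, 100, 2), 5)
        with pytest.raises(ValueError):
            maps.build_design(ind, collapse=[1, 1, 2])


class TestPartialCorrelationMap:
    def test_independent_envelope_gives_null_coefficients(self, rng):
        T = 5000
        ind = state_indicators(_random_path(4, T, 3), 4)
        d = maps.build_design(ind)
        env = rng.standard_normal((T, 6))
        beta = maps.partial_correlation_map(d, env)
        assert np.max(np.abs(beta)) < 3.0 / np.sqrt(T)

    def test_planted_boost_recovered_as_row_maximum(self, rng):
        T, K, M = 4000, 3, 5
        path = _random_path(K, T, 4)
        ind = state_indicators(path, K)
        env = rng.standard_normal((T, M)) * 0.3 + 1.0
        env[path == 2, 2] *= 2.0  # channel 2 boosted during state 2
        beta = maps.partial_correlation_map(maps.build_design(ind), env)
        assert beta[2, 1] > 0
        assert np.argmax(beta[2]) == 1

    def test_equals_residualization_partial_correlation(self, rng):
        """Algebraic oracle on a full-rank design: each coefficient equals
        the correlation of the residualized regressor with the residualized
        response, rescaled to the regression scale."""
        T, Kp = 200, 3
        d_raw = rng.standard_normal((T, Kp))  # full-rank continuous design
        design = maps.GLMDesign(
            raw=d_raw,
            matrix=(d_raw - d_raw.mean(0)) / d_raw.std(0),
            labels=["a", "b", "c"])
        y = rng.standard_normal((T, 2))
        beta = maps.partial_correlation_map(design, y)
        z = design.matrix
        yz = (y - y.mean(0)) / y.std(0)
        for k in range(Kp):
            others = np.delete(z, k, axis=1)
            proj = others @ np.linalg.lstsq(others, z[:, k], rcond=None)[0]
            rx = z[:, k] - proj
            for ch in range(2):
                proj_y = others @ np.linalg.lstsq(others, yz[:, ch], rcond=None)[0]
                ry = yz[:, ch] - proj_y
                expect = (rx @ ry) / (rx @ rx)
                assert np.isclose(beta[ch, k], expect, atol=1e-10)

    def test_affine_envelope_invariance(self, rng):
        T = 1000
        ind = state_indicators(_random_path(3, T, 5), 3)
        d = maps.build_design(ind)
        env = rng.standard_normal((T, 4))
        b1 = maps.partial_correlation_map(d, env)
        b2 = maps.partial_correlation_map(d, 7.0 * env + 3.0)
        assert np.allclose(b1, b2, atol=1e-10)

    def test_misaligned_axes_rejected(self, rng):
        ind = state_indicators(_random_path(3, 100, 6), 3)
        with pytest.raises(ValueError):
            maps.partial_correlation_map(maps.build_design(ind),
                                         rng.standard_normal((99, 4)))


class TestBandSpecificMaps:
    def test_band_selectivity(self, rng):
        """A modulation planted only in the alpha carrier shows in the alpha
        map and not in the theta map."""
        T, K = 6000, 3
        path = _random_path(K, T, 7)
        ind = state_indicators(path, K)
        theta_env = rng.standard_normal((T, 4)) * 0.3 + 1.0
        alpha_env = rng.standard_normal((T, 4)) * 0.3 + 1.0
        alpha_env[path == 1, 0] *= 2.0
        out = maps.band_specific_maps(maps.build_design(ind),
                                      {"theta": theta_env, "alpha": alpha_env})
        assert out["alpha"][0, 0] > 5 * abs(out["theta"][0, 0])

    def test_zero_depth_cohort_all_band_maps_null(self):
        cfg = sg.SynthConfig(n_subjects=1, duration_s=120.0, n_channels=6,
                             K=3, depth=0.0, seed=11)
        from netstates.envelope import BANDS, raw_to_envelope

        raws, gt = sg.simulate_cohort(cfg)
        trim = 20
        path = gt.paths[0][trim:-trim]
        ind = state_indicators(path, 3)
        envs = {b: raw_to_envelope(raws[0], cfg.fs_raw, b, orthogonalize=False)
                for b in ("theta", "alpha", "beta")}
        out = maps.band_specific_maps(maps.build_design(ind), envs)
        for b, m in out.items():
            assert np.max(np.abs(m)) < 6.0 / np.sqrt(path.size)


class TestAverageMaps:
    def test_identical_maps_unchanged(self, rng):
        m = rng.standard_normal((5, 3))
        assert np.allclose(maps.average_maps([m, m]), m)

    def test_absolute_averaging_resolves_sign_ambiguity(self, rng):
        m = rng.standard_normal((5, 3))
        out = maps.average_maps([m, -m], use_absolute=True)
        assert np.allclose(out, np.abs(m))
        plain = maps.average_maps([m, -m])
        assert np.allclose(plain, 0.0)


class TestHighRateMask:
    def test_mask_selects_high_occupancy_epochs(self):
        # state 1 concentrated in the second half
        path = np.concatenate([np.full(1000, 2), np.full(1000, 1)])
        mask = maps.high_rate_mask(path, 2, state=1, fs=20.0)
        assert mask.shape == (2000,)
        assert mask[1500:].all()
        assert not mask[:800].any()

    def test_masked_map_preserves_planted_sign_and_ranking(self, rng):
        T, K = 8000, 3
        path = _random_path(K, T, 8)
        ind = state_indicators(path, K)
        env = rng.standard_normal((T, 5)) * 0.3 + 1.0
        env[path == 1, 0] *= 2.5
        env[path == 1, 1] *= 1.5
        d = maps.build_design(ind)
        mask = maps.high_rate_mask(path, K, state=1, fs=20.0, quantile=0.5)
        beta = maps.partial_correlation_map(d, env, mask=mask)
        assert beta[0, 0] > beta[1, 0] > 0


class TestUltraslowRateMap:
    def test_planted_coupling_is_map_maximum(self):
        from netstates.metrics import occurrence_rate_timecourse

        cfg = sg.SynthConfig(n_subjects=1, duration_s=540.0, n_channels=6,
                             K=3, occupancy=[0.2, 0.4, 0.4],
                             self_transition=[0.8, 0.7, 0.7],
                             ultraslow_freq=0.05, ultraslow_gain=0.9,
                             ultraslow_state=1, seed=12)
        raws, gt = sg.simulate_cohort(cfg)
        rates = occurrence_rate_timecourse(gt.paths[0], 3, cfg.fs_env)
        # slow channel series: the planted modulator enters the coupled
        # state's channels; align to window starts
        from netstates.envelope import downsample_envelope, lowpass_ultraslow

        slow = lowpass_ultraslow(raws[0], cfg.fs_raw, axis=-1).T
        slow20 = downsample_envelope(slow, cfg.fs_raw, cfg.fs_env)[: rates.shape[0]]
        beta = maps.ultraslow_rate_map(rates, slow20)
        coupled_channels = cfg.topographies[0] > 0
        assert np.max(np.abs(beta)) == np.max(np.abs(beta[coupled_channels, 0]))

    def test_sign_flip_invariance_under_absolute_averaging(self, rng):
        rates = rng.random((500, 3))
        slow = rng.standard_normal((500, 4))
        b1 = maps.ultraslow_rate_map(rates, slow)
        b2 = maps.ultraslow_rate_map(rates, -slow)
        assert np.allclose(maps.average_maps([b1], use_absolute=True),
                           maps.average_maps([b2], use_absolute=True))

    def test_misaligned_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            maps.ultraslow_rate_map(rng.random((100, 2)),
                                    rng.standard_normal((99, 3)))


class TestSessionAverage:
    def test_constant_envelope(self):
        out = maps.session_average_amplitude({"theta": np.full((100, 3), 2.0)})
        assert np.allclose(out, 2.0)

    def test_equals_occupancy_weighted_state_means(self, rng):
        """Law of total expectation: the session mean equals the FO-weighted
        mean of within-state envelope means."""
        from netstates.metrics import fractional_occupancy

        T = 3000
        path = _random_path(3, T, 9)
        env = rng.random((T, 4)) + path[:, None]
        total = maps.session_average_amplitude({"wide": env})[:, 0]
        fo = fractional_occupancy(path, 3)
        per_state = np.stack([env[path == k + 1].mean(axis=0) for k in range(3)])
        assert np.allclose(total, fo @ per_state, atol=1e-10)
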