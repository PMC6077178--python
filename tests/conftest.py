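import numpy as np
import pytest

from netstates import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort shared by pipeline-level tests.

    3 subjects x 2 min, 12 channels, 4 states with distinct dwell times and
    occupancies — big enough to carry the planted structure, small enough to
    preprocess and fit in seconds.
    """
    occ = np.array([0.10, 0.30, 0.25, 0.35])
    dwell_ms = np.array([250.0, 150.0, 150.0, 200.0])
    cfg = sg.SynthConfig(
        n_subjects=3, duration_s=120.0, n_channels=12, K=4,
        occupancy=occ,
        self_transition=1.0 - 1000.0 / (20.0 * dwell_ms),
        depth=1.0, noise_sd=0.2, seed=77, group="demo",
    )
    raws, gt = sg.simulate_cohort(cfg)
    return cfg, raws, gt
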