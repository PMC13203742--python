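import numpy as np
import pytest

from astrocal import SimulationConfig, preprocess, simulate
from astrocal.metrics import align_truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A short low-resolution simulated video for structural tests."""
    cfg = SimulationConfig(width=96, height=96, duration=4.0, n_events=6, seed=7)
    noisy, truth = simulate(cfg)
    return cfg, noisy, truth


@pytest.fixture(scope="session")
def pipeline_run():
    """One full-scale replicate: simulate, preprocess, align ground truth.

    Uses a 15 s clip at the default 256x256 resolution and event density
    (97 events/min scaled to 24) so detector behavior matches the full-length
    study conditions while keeping the suite fast.
    """
    cfg = SimulationConfig(duration=15.0, n_events=24, seed=1)
    noisy, truth = simulate(cfg)
    pre = preprocess(noisy)
    tr = align_truth(truth.mask, 13, 1, pre.n_frames)
    ts = align_truth(truth.clean_signal, 13, 1, pre.n_frames)
    return cfg, pre, ts, tr
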