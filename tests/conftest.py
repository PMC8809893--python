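import numpy as np
import pytest

import lcpupil as lp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_session():
    """One simulated paired recording with default (coupled) settings."""
    cfg = lp.SimConfig(duration=3600.0, seed=42)
    train, trace, gt = lp.generate_session(cfg)
    return cfg, train, trace, gt


@pytest.fixture(scope="session")
def uncoupled_session():
    """Zero-gain session: pupil independent of spiking."""
    cfg = lp.SimConfig(duration=1800.0, seed=43, gain=0.0)
    train, trace, gt = lp.generate_session(cfg)
    return cfg, train, trace, gt
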