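import numpy as np
import pytest

from fermxfer.synthetic import (
    HeterogeneityConfig,
    KineticsConfig,
    simulate_campaign,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_campaign():
    """Three batches simulated with the default kinetics (seed 42)."""
    cfg = KineticsConfig(seed=42)
    return simulate_campaign(cfg, 3)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free kinetics for deterministic trajectory checks."""
    return KineticsConfig(noise_sd_aux=0.0, noise_sd_target=0.0, seed=7)


@pytest.fixture
def no_jitter():
    return HeterogeneityConfig(kinetic_jitter_sd=0.0)
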