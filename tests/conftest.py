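import numpy as np
import pytest

from sofismooth.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A desk-scale simulation: small field, short movie, sparse emitters."""
    return SimulationConfig(
        fov_pixels=(8, 8), n_frames=100, n_fluorophores=400, n_lines=4,
        tau_bleach_s=None,
    )


@pytest.fixture
def bleached_stack_16():
    """Simulated 16x16x300 camera stack with fast photodestruction."""
    from sofismooth.simulate import simulate_dataset

    config = SimulationConfig(
        fov_pixels=(16, 16), n_frames=300, n_fluorophores=5000,
        tau_bleach_s=1.1,
    )
    stack, _, _ = simulate_dataset(config, seed=20240601)
    return stack.astype(float)
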