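import numpy as np
import pytest

from shuntnet import ConnectivityConfig, StimulusSpec, build_network


@pytest.fixture(scope="session")
def small_config():
    """Tiny deterministic network (10E+3I layer one, 10E layer two)."""
    return ConnectivityConfig(
        n_v1_excitatory=10,
        n_v1_inhibitory=3,
        n_v2_excitatory=10,
        recurrent_sd=2.0,
        feedforward_sd=1.5,
        random_seed=42,
    )


@pytest.fixture()
def small_network(small_config):
    return build_network(small_config)


@pytest.fixture(scope="session")
def small_stimulus():
    return StimulusSpec(center_orientation=90.0, peak_amplitude=1.5,
                        profile_width=2.0, duration=200.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
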