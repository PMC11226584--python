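import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import braingap as bg

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template16():
    return bg.make_template((16, 16, 16), seed=1)


@pytest.fixture(scope="session")
def tiny_config():
    return bg.SimConfig(
        grid_shape=(12, 12, 12), n_train=60, n_target=150,
        n_signal_clusters=2, n_proteins=150, n_true_proteins=8,
        protein_effect_sd=0.3, noise_sd=0.04, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """One small but complete synthetic study, shared across tests."""
    return bg.simulate_study(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
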