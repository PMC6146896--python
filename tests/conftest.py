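import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 20-sample, coarse-grid synthetic dataset shared by fast tests."""
    from libscal import simulate_dataset, small_config

    cfg = small_config(
        group_sizes=(4, 4, 4, 4, 4), n_channels=1500, replicates=2, seed=77
    )
    return simulate_dataset(cfg)
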