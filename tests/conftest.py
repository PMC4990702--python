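import numpy as np
import pytest

from beepersist.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A miniature study: quick to simulate and fit, same structure."""
    return SimConfig(
        n_forager=4,
        n_nonforager=3,
        n_sites=25,
        cells_per_site=3,
        n_regions=3,
        n_filler_species=40,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
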