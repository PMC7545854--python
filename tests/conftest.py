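import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolscan.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-stock dataset shared across tests (truth + counts)."""
    cfg = SimulationConfig(
        n_stocks=4, pools_per_stock=2, n_sites=500, drift_F=0.1, seed=11
    )
    truth, matrix = simulate_dataset(cfg)
    return cfg, truth, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
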