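import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hashdemux as hd
from hashdemux.datasets import load_eightpool_ca_contingency

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ca_contingency() -> hd.ContingencyTable:
    """Bundled carrier-fraction hashing-vs-genotype contingency (12 884 cells)."""
    return load_eightpool_ca_contingency()


@pytest.fixture(scope="session")
def ca_cells(ca_contingency):
    """Per-cell expansion of the carrier-fraction contingency."""
    return hd.expand_contingency_to_cells(ca_contingency)


@pytest.fixture(scope="session")
def sim_default():
    """Default eight-sample, 5000-cell synthetic experiment (seed 0)."""
    cfg = hd.SimulationConfig(seed=0)
    return cfg, *hd.simulate_experiment(cfg)


@pytest.fixture()
def tiny_counts() -> hd.CountMatrix:
    return hd.CountMatrix(
        np.array([[5, 0], [9, 1], [2, 2]]),
        ["AAAC-1", "AAAG-1", "AAAT-1"],
        ["H1", "H2"],
    )
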