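import numpy as np
import pytest

from svimpute.config import HMMParams, SimulationConfig
from svimpute.simulate import simulate_panel


def tiny_sim_config(**overrides) -> SimulationConfig:
    """A 2 Mb, 8-haplotype panel config small enough for exhaustive checks."""
    base = dict(
        n_haplotypes=8,
        chrom_length=2_000_000,
        n_snvs=30,
        n_svs_per_class={"DEL": 4, "DUP": 2, "INV": 1},
        sv_length_bounds={
            "DEL": (100, 5_000),
            "DUP": (140, 5_000),
            "INV": (1_100, 5_000),
        },
        seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def tiny_config():
    return tiny_sim_config()


@pytest.fixture
def tiny_panel(tiny_config):
    panel, variants = simulate_panel(tiny_config)
    return panel


@pytest.fixture(scope="session")
def default_panel():
    """The desk-scale study panel: 100 haplotypes, 2000 SNVs, 130 SVs."""
    config = SimulationConfig(seed=7)
    panel, variants = simulate_panel(config)
    return config, panel, variants


@pytest.fixture
def hmm_params():
    return HMMParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
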