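import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynamark as dm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions: 3 conditions, 200 genes, 3-fold planted
    enrichment, ~40 bins per gene window."""
    return dm.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    tracks, genes, truth, chrom_sizes = dm.simulate_dataset(sim_config)
    cpm = {
        cond: {ch: dm.normalize_cpm(t) for ch, t in channels.items()}
        for cond, channels in tracks.items()
    }
    return cpm, genes, truth, chrom_sizes


@pytest.fixture(scope="session")
def gene_assignments(sim_config, sim_dataset):
    """Gene-based pattern calls on the packaged synthetic dataset."""
    tracks, genes, truth, chrom_sizes = sim_dataset
    return dm.call_gene_patterns(
        tracks,
        genes,
        dm.WindowSpec(),
        dm.CallParameters(),
        chrom_sizes,
        conditions=list(sim_config.conditions),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
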