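import numpy as np
import pytest

import polstate as ps


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared across the suite."""
    genome, truth = ps.simulate_genome(ps.SimulationConfig(seed=7))
    return genome, truth


@pytest.fixture(scope="session")
def default_tracks(default_sim):
    genome, truth = default_sim
    total = ps.simulate_total_coverage(genome, truth)
    phospho = ps.simulate_phospho_tracks(genome, truth, total)
    return total, phospho


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """8-state fit on the default simulation's idealized enrichment matrix."""
    genome, truth = default_sim
    X = truth.enrichment_matrix()
    res = ps.PhosphoHMM(X, n_states=8).fit(seed=1)
    res.label_states(truth.reference)
    return X, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
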