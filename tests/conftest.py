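import pytest

from hybridase import simulate
from hybridase.model import HybridAseModel


@pytest.fixture(scope="session")
def default_config():
    """Moderate-size default scenario shared across test modules."""
    return simulate.ScenarioConfig(n_orthologs=600, seed=17)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return simulate.build_truth(default_config)


@pytest.fixture(scope="session")
def default_experiment(default_config, default_truth):
    return simulate.simulate_counts(default_truth, default_config)


@pytest.fixture(scope="session")
def fitted(default_experiment):
    """Full model fit on the default scenario (shared: fitting is the
    expensive step)."""
    return HybridAseModel.from_simulation(default_experiment).fit()
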