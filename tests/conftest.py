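import pytest

from coaldate import SCENARIOS, SimulationConfig, simulate_replicates
from coaldate.synthetic_fixtures import worked_trees


@pytest.fixture(scope="session")
def trees():
    """The hand-built worked trees with exact node ages."""
    return worked_trees()


@pytest.fixture(scope="session")
def deep_config():
    return SCENARIOS["deep"]


@pytest.fixture(scope="session")
def recent_config():
    return SCENARIOS["recent"]


@pytest.fixture(scope="session")
def deep_trees_small():
    """200 deep-divergence genealogies shared across structural tests."""
    cfg = SimulationConfig(pop_sizes=(1, 10), theta=2.0, t_join=10.0, n_reps=200, seed=11)
    return simulate_replicates(cfg)


@pytest.fixture(scope="session")
def recent_trees_small():
    cfg = SimulationConfig(pop_sizes=(1, 10), theta=2.0, t_join=0.01, n_reps=200, seed=12)
    return simulate_replicates(cfg)
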