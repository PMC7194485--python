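import pytest
from hypothesis import settings

from omicsviz import FixtureConfig, connect, demo_tables, make_network, make_table

settings.register_profile("suite", derandomize=True, max_examples=120, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def demo_pair():
    """Small worked-example table + network with matching key values."""
    return demo_tables()


@pytest.fixture
def demo_connection(demo_pair):
    table, network = demo_pair
    return connect(table, network, net_key_col="query term", table_key_col="UniProt")


@pytest.fixture
def fixture_config():
    return FixtureConfig(n_proteins=12, sites_per_protein=2.0, seed=7)


@pytest.fixture
def synthetic_table(fixture_config):
    return make_table(fixture_config)


@pytest.fixture
def synthetic_network(synthetic_table, fixture_config):
    return make_network(synthetic_table, edge_prob=fixture_config.edge_prob,
                        seed=fixture_config.seed)
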