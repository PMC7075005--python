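import pytest

from herbnet import project, sample_network


@pytest.fixture(scope="session")
def fixture_map():
    """The 7-target / 6-pathway worked-example bipartite map."""
    return sample_network()


@pytest.fixture(scope="session")
def fixture_graph(fixture_map):
    """Its one-mode TPT projection (7 nodes, 8 edges)."""
    return project(fixture_map)
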