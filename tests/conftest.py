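import networkx as nx
import pytest

from topas.synthetic import SuiteConfig, generate_suite


@pytest.fixture
def path_graph() -> nx.Graph:
    """a - x - b : the smallest instance needing one connector."""
    return nx.Graph([("a", "x"), ("x", "b")])


@pytest.fixture
def square_graph() -> nx.Graph:
    """Two parallel seed-seed paths a-x-b and a-y-b plus a pendant a-z."""
    return nx.Graph([("a", "x"), ("x", "b"), ("a", "y"), ("y", "b"), ("a", "z")])


@pytest.fixture(scope="session")
def planted_suite():
    """The standard synthetic study condition: 100 planted-module instances
    on 2000-node scale-free networks (m=3, 20 seeds, 8 hidden connectors,
    d=2), master seed 0. Session-scoped: generation takes a few seconds."""
    return generate_suite(SuiteConfig())


@pytest.fixture(scope="session")
def small_suite():
    """A lighter batch for per-module property tests."""
    return generate_suite(SuiteConfig(n_instances=10, n_nodes=400, m=2, n_seeds=8, n_hidden=4))
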