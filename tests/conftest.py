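import networkx as nx
import pytest

from pathreach.simulate import SyntheticConfig, simulate_scenario


@pytest.fixture(scope="session")
def planted_scenario():
    """One fully planted synthetic scenario shared across tests (seed-fixed)."""
    cfg = SyntheticConfig(seed=42, enrichment=1.0)
    net, scenario = simulate_scenario(cfg)
    return cfg, net, scenario


@pytest.fixture()
def random_graph():
    """A 30-node Erdos-Renyi graph with string node names, seed-fixed."""
    g = nx.erdos_renyi_graph(30, 0.15, seed=5)
    return nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
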