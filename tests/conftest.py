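import networkx as nx
import numpy as np
import pytest

from riverscape import synthetic as syn


@pytest.fixture
def chain_graph():
    """Textbook AEM chain: origin -> s1 -> s2 -> s3."""
    g = nx.DiGraph()
    g.add_edge("o", "s1", weight=1.0)
    g.add_edge("s1", "s2", weight=1.0)
    g.add_edge("s2", "s3", weight=1.0)
    for n in g.nodes:
        g.nodes[n]["kind"] = "origin" if g.in_degree(n) == 0 else "station"
    return g


def random_tree(n_sites: int, seed: int) -> nx.DiGraph:
    """Random rooted tree DAG with one origin and n_sites stations."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_node("o", kind="origin")
    g.add_edge("o", "s00", weight=1.0)
    g.nodes["s00"]["kind"] = "station"
    for i in range(1, n_sites):
        parent = f"s{int(rng.integers(0, i)):02d}"
        child = f"s{i:02d}"
        g.add_edge(parent, child, weight=1.0)
        g.nodes[child]["kind"] = "station"
    return g


@pytest.fixture
def small_river():
    """A 6-transect, 2-lane river with two contrasting tributaries."""
    cfg = syn.RiverConfig(
        n_transects=6,
        stations_per_transect=2,
        tributaries=(
            syn.Tributary(2, 500.0, syn.Endmember(acdom340=20.0, tripton=2.0, srp=30.0)),
            syn.Tributary(7, 300.0, syn.Endmember(acdom340=5.0, tripton=8.0, srp=60.0)),
        ),
        seed=7,
    )
    return syn.simulate_river(cfg)
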