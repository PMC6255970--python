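import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connected_graph(rng, n, p=0.3, prefix="n"):
    """Connected gnp graph with string node names and random edge distances."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
    comps = sorted(nx.connected_components(g), key=min)
    for c1, c2 in zip(comps, comps[1:]):
        g.add_edge(min(c1), min(c2))
    g = nx.relabel_nodes(g, {v: f"{prefix}{v:03d}" for v in g})
    for u, v in g.edges:
        g.edges[u, v]["distance"] = float(rng.random())
    return g
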