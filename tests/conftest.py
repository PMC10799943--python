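import networkx as nx
import pytest

from tcnbtopo import SimpleGraph, tcnb_partition


@pytest.fixture(scope="session")
def spec():
    return tcnb_partition()


def random_simple_graph(seed: int, max_n: int = 30) -> SimpleGraph:
    """Deterministic Erdos-Renyi graph for oracle checks (n <= max_n)."""
    rng_n = 3 + seed % (max_n - 2)
    p = 0.15 + (seed % 7) * 0.1
    g = nx.gnp_random_graph(rng_n, p, seed=seed)
    return SimpleGraph.from_networkx(g)
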