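import networkx as nx
import numpy as np
import pytest


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    """Seeded G(n, p) with integer node labels 0..n-1."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def relabel_str(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {v: f"N{v:03d}" for v in g.nodes})


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def planted_interactome():
    """200-node ER graph with one planted 5-clique, plus its ground truth."""
    from crossnet import InteractomeSimSpec, gen_interactome

    return gen_interactome(
        InteractomeSimSpec(n_nodes=200, density_param=0.03, planted_cliques=(5,), seed=42)
    )
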