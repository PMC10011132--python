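import networkx as nx
import pytest

from netexpand.graph_core import Interactome
from netexpand import (
    generate_planted_network,
    generate_trait_seeds,
    run_ppr,
)


@pytest.fixture(scope="module")
def planted():
    """Default desk-scale planted-partition scenario with one seeded trait."""
    net, truth = generate_planted_network(rng_seed=42)
    seeds = generate_trait_seeds(truth, n_traits=1, rng_seed=43)[0]
    return net, truth, seeds


@pytest.fixture(scope="module")
def planted_result(planted):
    net, truth, seeds = planted
    return run_ppr(net, seeds)


def graph_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return Interactome(g)


@pytest.fixture
def two_cliques_bridged():
    edges = []
    for base in ("A", "B"):
        ns = [f"{base}{i}" for i in range(5)]
        edges += [(ns[i], ns[j]) for i in range(5) for j in range(i + 1, 5)]
    edges.append(("A0", "B0"))
    return graph_from_edges(edges)
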