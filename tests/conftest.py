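import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from syncgame import GameParameters, Topology, assign_costs, grid_layout


def topology_from_networkx(g: nx.Graph, kind: str = "custom") -> Topology:
    """Wrap an arbitrary simple graph for use with the dynamics."""
    adj = sp.csr_array(nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes), dtype=np.int8))
    return Topology(kind=kind, adjacency=adj)


def star_topology(n_leaves: int) -> Topology:
    """Node 0 is the hub; handy for hand-computed payoff sums."""
    return topology_from_networkx(nx.star_graph(n_leaves))


@pytest.fixture
def default_params() -> GameParameters:
    """Table-style defaults: d=10 phases, cost 10, selection strength 1."""
    return GameParameters(b0=20, beta0=15, cost=10.0, d=10, delta=1.0)


@pytest.fixture
def small_grid():
    return grid_layout(4, 3)


@pytest.fixture
def nn4_costed():
    from syncgame import nearest_neighbor_4

    return assign_costs(nearest_neighbor_4(grid_layout(5, 5)), 10.0, "uniform")
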