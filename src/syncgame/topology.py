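"""Connection topologies for oscillators placed on a planar integer grid.

Four generators are provided: all-to-all, the 4-nearest-neighbor (von
Neumann) and 8-nearest-neighbor (Moore) lattices, and a probabilistic
spatial topology in which each pair of grid points is joined independently
with probability ``1 / (distance + gamma)``, ``distance`` being the
Euclidean distance between the two grid points — nearby oscillators
connect often, distant ones rarely, with ``gamma`` controlling overall
density.  Adjacency is a symmetric 0/1 matrix with zero diagonal, stored
sparse.

Also here: per-node communication costs (uniform, or scaled by relative
degree so the mean cost equals the base cost), and the two summary metrics
used to characterize the random ensembles — average local clustering and
average shortest-path length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist

__all__ = [
    "GridLayout",
    "Topology",
    "grid_layout",
    "all_to_all",
    "nearest_neighbor_4",
    "nearest_neighbor_8",
    "probabilistic_spatial",
    "edge_probability",
    "assign_costs",
    "clustering_coefficient",
    "average_path_length",
    "ensemble_metrics",
    "make_topology",
]

TOPOLOGY_KINDS = ("all_to_all", "nn4", "nn8", "probabilistic_spatial")


@dataclass(frozen=True)
class GridLayout:
    """``width x height`` integer grid, 1-based coordinates, row-major order.

    Node ``i`` (0-based) sits at ``(1 + i % width, 1 + i // width)``: the
    first row is ``(1,1), (2,1), ..., (width,1)``.
    """

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.width}x{self.height}")

    @property
    def n(self) -> int:
        return self.width * self.height

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) integer array of (x, y) pairs in node order."""
        i = np.arange(self.n)
        return np.column_stack((1 + i % self.width, 1 + i // self.width))

    def node_at(self, x: int, y: int) -> int:
        if not (1 <= x <= self.width and 1 <= y <= self.height):
            raise ValueError(f"({x},{y}) outside {self.width}x{self.height} grid")
        return (y - 1) * self.width + (x - 1)


def grid_layout(width: int, height: int) -> GridLayout:
    """Planar arrangement of ``width*height`` oscillators on the integer grid."""
    return GridLayout(width=width, height=height)


@dataclass
class Topology:
    """A symmetric, loop-free 0/1 connection pattern over ``n`` oscillators."""

    kind: str
    adjacency: sp.csr_array = field(repr=False)
    layout: GridLayout | None = None
    gamma: float | None = None
    node_costs: np.ndarray | None = field(default=None, repr=False)
    cost_mode: str | None = None

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    @property
    def isolated_count(self) -> int:
        return int((self.degrees == 0).sum())

    def neighbors(self, i: int) -> np.ndarray:
        row = self.adjacency.indptr
        return self.adjacency.indices[row[i]: row[i + 1]]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_scipy_sparse_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    # --- persistence ---------------------------------------------------
    def metadata(self) -> dict:
        return {
            "kind": self.kind,
            "n": self.n,
            "width": self.layout.width if self.layout else None,
            "height": self.layout.height if self.layout else None,
            "gamma": self.gamma,
            "cost_mode": self.cost_mode,
        }

    def write_edge_list(self, path: str | Path) -> None:
        """One ``u v`` pair (1-based) per line, JSON metadata in a '#' header."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.metadata()) + "\n")
            for u, v in zip(coo.row, coo.col):
                fh.write(f"{u + 1} {v + 1}\n")

    @staticmethod
    def read_edge_list(path: str | Path) -> "Topology":
        meta: dict = {}
        edges: list[tuple[int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    meta = json.loads(line[1:])
                    continue
                u, v = line.split()
                edges.append((int(u) - 1, int(v) - 1))
        n = meta.get("n")
        if n is None:
            n = 1 + max(max(e) for e in edges) if edges else 0
        adj = _edges_to_csr(n, edges)
        layout = None
        if meta.get("width") and meta.get("height"):
            layout = GridLayout(meta["width"], meta["height"])
        return Topology(kind=meta.get("kind", "custom"), adjacency=adj,
                        layout=layout, gamma=meta.get("gamma"))

    def write_matrix_market(self, path: str | Path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.adjacency.tocoo())


def _edges_to_csr(n: int, edges: list[tuple[int, int]]) -> sp.csr_array:
    if not edges:
        return sp.csr_array((n, n), dtype=np.int8)
    arr = np.asarray(edges)
    rows = np.concatenate([arr[:, 0], arr[:, 1]])
    cols = np.concatenate([arr[:, 1], arr[:, 0]])
    data = np.ones(rows.size, dtype=np.int8)
    adj = sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = 1  # collapse any duplicates
    return adj


def all_to_all(n: int) -> Topology:
    """Complete graph: every oscillator connected to every other one."""
    if n < 2:
        raise ValueError(f"all_to_all needs n >= 2, got {n}")
    adj = sp.csr_array(np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8))
    return Topology(kind="all_to_all", adjacency=adj)


def _lattice(layout: GridLayout, offsets: list[tuple[int, int]], kind: str) -> Topology:
    w, h = layout.width, layout.height
    coords = layout.coordinates
    x, y = coords[:, 0], coords[:, 1]
    rows, cols = [], []
    for dx, dy in offsets:
        ok = (x + dx >= 1) & (x + dx <= w) & (y + dy >= 1) & (y + dy <= h)
        src = np.flatnonzero(ok)
        dst = src + dx + dy * w
        rows.append(src)
        cols.append(dst)
    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    data = np.ones(rows_a.size, dtype=np.int8)
    adj = sp.coo_array((data, (rows_a, cols_a)), shape=(layout.n, layout.n)).tocsr()
    adj.data[:] = 1
    return Topology(kind=kind, adjacency=adj, layout=layout)


def nearest_neighbor_4(layout: GridLayout) -> Topology:
    """Von Neumann lattice: axial neighbors only; edge nodes omit missing links."""
    return _lattice(layout, [(1, 0), (-1, 0), (0, 1), (0, -1)], "nn4")


def nearest_neighbor_8(layout: GridLayout) -> Topology:
    """Moore lattice: axial plus diagonal neighbors."""
    offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    return _lattice(layout, offsets, "nn8")


def edge_probability(distance: float, gamma: float) -> float:
    """Connection probability ``1 / (distance + gamma)`` for one pair of
    nodes at the given Euclidean distance, capped at 1 (reached only for
    adjacent pairs at ``gamma = 0``)."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    p = 1.0 / (distance + gamma) if distance + gamma > 0 else 1.0
    return min(p, 1.0)


def probabilistic_spatial(
    layout: GridLayout, gamma: float, rng: np.random.Generator | int
) -> Topology:
    """Distance-dependent random graph on the grid.

    Each unordered pair of distinct nodes at Euclidean distance ``r`` is
    joined independently, exactly once, with probability
    ``1 / (r + gamma)``.  At ``gamma = 0`` adjacent pairs connect with
    probability 1.  Isolated nodes are possible (rare at ``gamma = 10``)
    and are reported, not regenerated; the dynamics treats them as inert.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coords = layout.coordinates.astype(np.float64)
    n = layout.n
    if n < 2:
        return Topology(kind="probabilistic_spatial",
                        adjacency=sp.csr_array((n, n), dtype=np.int8),
                        layout=layout, gamma=gamma)
    dist = pdist(coords, metric="euclidean")  # condensed upper-triangle order
    p = np.minimum(1.0 / (dist + gamma), 1.0)
    hit = rng.random(p.size) < p
    iu, ju = np.triu_indices(n, k=1)
    rows, cols = iu[hit], ju[hit]
    adj = _edges_to_csr(n, list(zip(rows.tolist(), cols.tolist()))) if rows.size else \
        sp.csr_array((n, n), dtype=np.int8)
    return Topology(kind="probabilistic_spatial", adjacency=adj, layout=layout, gamma=gamma)


def assign_costs(topology: Topology, base_cost: float, mode: str = "uniform") -> Topology:
    """Attach per-node communication costs.

    ``uniform`` gives every node ``base_cost``.  ``degree_adjusted`` gives
    node ``i`` the cost ``base_cost * N(i) / mu`` with ``mu`` the mean
    degree, so the mean cost over nodes equals ``base_cost`` and runs remain
    comparable across cost structures; on regular graphs the two modes
    coincide.
    """
    if base_cost < 0:
        raise ValueError(f"base_cost must be >= 0, got {base_cost}")
    if mode == "uniform":
        costs = np.full(topology.n, float(base_cost))
    elif mode == "degree_adjusted":
        deg = topology.degrees.astype(np.float64)
        mu = deg.mean()
        if mu == 0:
            raise ValueError("degree-adjusted costs undefined on an edgeless graph")
        costs = base_cost * deg / mu
    else:
        raise ValueError(f"unknown cost mode {mode!r}")
    return replace(topology, node_costs=costs, cost_mode=mode)


def clustering_coefficient(topology: Topology) -> float:
    """Mean local clustering coefficient; nodes of degree < 2 contribute 0.

    For each node the local coefficient is the number of triangles through
    it divided by the number of pairs of its neighbors; triangles are
    counted with sparse matrix products so dense-ensemble computations stay
    cheap.
    """
    if topology.n == 0:
        raise ValueError("empty topology")
    a = topology.adjacency.astype(np.int64)
    triangles = np.asarray(a.multiply(a @ a).sum(axis=1)).ravel() / 2.0
    deg = topology.degrees.astype(np.float64)
    pairs = deg * (deg - 1.0) / 2.0
    local = np.divide(triangles, pairs, out=np.zeros_like(pairs), where=pairs > 0)
    return float(local.mean())


def average_path_length(topology: Topology) -> float:
    """Mean shortest-path length over connected unordered node pairs.

    If the graph is disconnected, a warning is issued and the mean over the
    reachable pairs is returned.
    """
    n = topology.n
    if n < 2:
        raise ValueError("average path length needs n >= 2")
    dist = shortest_path(topology.adjacency, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    vals = dist[iu]
    finite = np.isfinite(vals)
    if not finite.all():
        warnings.warn(
            f"graph disconnected: {int((~finite).sum())} of {vals.size} pairs unreachable; "
            "averaging over connected pairs",
            stacklevel=2,
        )
    if not finite.any():
        raise ValueError("no connected pairs")
    return float(vals[finite].mean())


def ensemble_metrics(
    width: int = 40,
    height: int = 40,
    gamma: float = 10.0,
    instances: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Clustering / path-length / degree averages over an ensemble of
    probabilistic spatial instances, each generated with a fresh stream."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    layout = grid_layout(width, height)
    clus, apl, deg = [], [], []
    n_disconnected = 0
    for _ in range(instances):
        topo = probabilistic_spatial(layout, gamma, rng)
        clus.append(clustering_coefficient(topo))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            apl.append(average_path_length(topo))
            n_disconnected += int(bool(caught))
        deg.append(topo.mean_degree)
    return {
        "instances": instances,
        "mean_clustering": float(np.mean(clus)),
        "mean_path_length": float(np.mean(apl)),
        "mean_degree": float(np.mean(deg)),
        "disconnected_instances": n_disconnected,
    }


def make_topology(
    kind: str,
    width: int = 40,
    height: int = 40,
    gamma: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> Topology:
    """Dispatch on topology kind; the grid kinds ignore ``gamma`` and ``rng``."""
    if kind == "all_to_all":
        return all_to_all(width * height)
    layout = grid_layout(width, height)
    if kind == "nn4":
        return nearest_neighbor_4(layout)
    if kind == "nn8":
        return nearest_neighbor_8(layout)
    if kind == "probabilistic_spatial":
        if rng is None:
            raise ValueError("probabilistic_spatial requires an rng or seed")
        return probabilistic_spatial(layout, gamma, rng)
    raise ValueError(f"unknown topology kind {kind!r}; choose from {TOPOLOGY_KINDS}")
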