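"""Graph primitives shared by every pipeline stage.

The analysis graphs are small (hundreds of nodes): a protein-protein
interaction subnetwork induced on an immunome-style gene list, either
undirected or — for the signaling variant — directed with signed arcs.
This module holds the node/edge container, all-pairs hop distances,
connected components, and the topology summary (mean degree, diameter,
clustering, power-law degree exponent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

SIGN_CODES = ("+", "-", "0")


def _norm_edge(a: str, b: str, directed: bool) -> Edge:
    return (a, b) if directed else (min(a, b), max(a, b))


@dataclass
class GeneNetwork:
    """A simple graph (or digraph) over gene symbols.

    Undirected edges are stored order-independently as sorted pairs;
    self-loops and parallel edges are rejected at construction.  ``signs``
    optionally maps each *undirected* edge to one of ``+``/``-``/``0``
    (activation / inhibition / physical interaction) for the signaling
    variant prior to orientation.
    """

    nodes: set[str]
    edges: set[Edge]
    directed: bool = False
    signs: dict[Edge, str] | None = None

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = {_norm_edge(a, b, self.directed) for a, b in self.edges}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside node set")
        if self.signs is not None:
            self.signs = {
                _norm_edge(a, b, self.directed): s for (a, b), s in self.signs.items()
            }
            for e, s in self.signs.items():
                if s not in SIGN_CODES:
                    raise ValueError(f"unknown sign code {s!r} on edge {e}")

    @classmethod
    def from_edges(
        cls,
        edges,
        directed: bool = False,
        signs: dict[Edge, str] | None = None,
        extra_nodes=(),
    ) -> "GeneNetwork":
        nodes = set(extra_nodes)
        kept: set[Edge] = set()
        for a, b in edges:
            nodes.update((a, b))
            if a != b:
                kept.add(_norm_edge(a, b, directed))
        return cls(nodes=nodes, edges=kept, directed=directed, signs=signs)

    # -- conversions -------------------------------------------------------

    def to_networkx(self):
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def adjacency(self, nodes: list[str] | None = None) -> np.ndarray:
        """Dense 0/1 adjacency A with A[i, j] = 1 iff arc/edge i->j exists."""
        order = self.sorted_nodes() if nodes is None else list(nodes)
        idx = {v: i for i, v in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for u, v in self.edges:
            if u in idx and v in idx:
                a[idx[u], idx[v]] = 1.0
                if not self.directed:
                    a[idx[v], idx[u]] = 1.0
        return a

    def degree(self) -> dict[str, int]:
        d = dict.fromkeys(self.nodes, 0)
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DistanceMatrix:
    """Hop distances for every ordered node pair; -1 marks unreachable."""

    nodes: list[str]
    matrix: np.ndarray  # int, shape (n, n), -1 where unreachable

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.nodes)}

    def d(self, a: str, b: str) -> int:
        return int(self.matrix[self.index[a], self.index[b]])

    def reachable(self, a: str, b: str) -> bool:
        return self.matrix[self.index[a], self.index[b]] >= 0


@dataclass
class TopologySummary:
    average_degree: float
    diameter: int
    avg_clustering: float
    degree_exponent: float
    n_components: int = 1
    component_diameters: dict[int, int] = field(default_factory=dict)


def all_pairs_distances(net: GeneNetwork) -> DistanceMatrix:
    """BFS shortest-path hop lengths for every ordered pair.

    Unreachable pairs are flagged (-1) rather than given an infinite value,
    so downstream distance sums can exclude them explicitly.
    """
    if not net.nodes:
        raise ValueError("empty network")
    order = net.sorted_nodes()
    idx = {v: i for i, v in enumerate(order)}
    g = net.to_networkx()
    m = np.full((len(order), len(order)), -1, dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = idx[src]
        for dst, d in lengths.items():
            m[i, idx[dst]] = d
    return DistanceMatrix(nodes=order, matrix=m)


def connected_components(net: GeneNetwork) -> list[set[str]]:
    """Partition of nodes into (weakly) connected components, largest first."""
    g = net.to_networkx()
    comps = (
        nx.weakly_connected_components(g) if net.directed else nx.connected_components(g)
    )
    return sorted((set(c) for c in comps), key=lambda c: (-len(c), min(c)))


def fit_degree_exponent(degrees) -> float:
    """Power-law slope gamma from least squares on the log-log degree histogram.

    Regresses log10(count) on log10(degree) over nonzero degrees with nonzero
    counts and returns the negated slope, the convention under which a
    k^(-gamma) distribution yields gamma.
    """
    degrees = [d for d in degrees if d > 0]
    if not degrees:
        raise ValueError("no nonzero degrees to fit")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 2:
        raise ValueError("degree histogram has fewer than two distinct degrees")
    slope = np.polyfit(np.log10(ks), np.log10(counts), 1)[0]
    return float(-slope)


def topology_summary(net: GeneNetwork) -> TopologySummary:
    """Average degree, diameter (largest component), clustering and gamma.

    Directed networks are summarized on their undirected projection, and for
    disconnected networks the diameter of every component with >= 2 nodes is
    reported alongside the largest component's.
    """
    if net.n_nodes < 2:
        raise ValueError("topology summary needs >= 2 nodes")
    g = net.to_networkx()
    if net.directed:
        g = g.to_undirected()
    if g.number_of_edges() == 0:
        raise ValueError("all nodes isolated: no diameter")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    comp_diams = {
        i: nx.diameter(g.subgraph(c))
        for i, c in enumerate(comps)
        if len(c) >= 2
    }
    degs = [d for _, d in g.degree()]
    try:
        gamma = fit_degree_exponent(degs)
    except ValueError:
        gamma = float("nan")  # regular graph: slope undefined
    return TopologySummary(
        average_degree=2 * g.number_of_edges() / g.number_of_nodes(),
        diameter=comp_diams[0],
        avg_clustering=float(nx.average_clustering(g)),
        degree_exponent=gamma,
        n_components=len(comps),
        component_diameters=comp_diams,
    )
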