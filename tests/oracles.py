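"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — dense Floyd–Warshall, exhaustive
shortest-path enumeration, Laplacian pseudoinverse resistances, truncated
series summation, full eigendecomposition — and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

INF = float("inf")


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = len(a)
    d = np.where(a > 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_shortest_paths(g: nx.Graph, s, t) -> list[tuple]:
    """All shortest s-t paths via exhaustive search."""
    if not nx.has_path(g, s, t):
        return []
    return [tuple(p) for p in nx.all_shortest_paths(g, s, t)]


def betweenness_by_enumeration(g: nx.Graph) -> dict:
    """SP betweenness summed over unordered pairs, endpoints excluded."""
    nodes = sorted(g.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(g, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def eccentricity_closeness_brute(g: nx.Graph) -> tuple[dict, dict]:
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    d = floyd_warshall(a)
    ecc, clo = {}, {}
    for i, v in enumerate(nodes):
        finite = d[i][np.isfinite(d[i])]
        ecc[v] = 1.0 / finite.max()
        clo[v] = 1.0 / finite.sum()
    return ecc, clo


def centroid_brute(g: nx.Graph) -> dict:
    """Triple-loop centroid values on a connected graph."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    d = floyd_warshall(a)
    idx = {v: i for i, v in enumerate(nodes)}
    out = {}
    for i_v in nodes:
        best = INF
        for j_v in nodes:
            if j_v == i_v:
                continue
            gij = sum(
                1 for w in nodes if w not in (i_v, j_v)
                and d[idx[w], idx[i_v]] < d[idx[w], idx[j_v]]
            )
            gji = sum(
                1 for w in nodes if w not in (i_v, j_v)
                and d[idx[w], idx[j_v]] < d[idx[w], idx[i_v]]
            )
            best = min(best, gij - gji)
        out[i_v] = best
    return out


def laplacian_pinv(g: nx.Graph, nodes) -> np.ndarray:
    a = nx.to_numpy_array(g, nodelist=nodes)
    return np.linalg.pinv(np.diag(a.sum(1)) - a)


def cf_closeness_brute(g: nx.Graph) -> dict:
    """(n-1) / sum of effective resistances, connected graph."""
    nodes = sorted(g.nodes)
    lp = laplacian_pinv(g, nodes)
    n = len(nodes)
    out = {}
    for i, v in enumerate(nodes):
        tot = sum(lp[i, i] + lp[j, j] - 2 * lp[i, j] for j in range(n) if j != i)
        out[v] = (n - 1) / tot
    return out


def cf_betweenness_brute(g: nx.Graph) -> dict:
    """Pair-averaged current through each node, naive per-pair solves."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    lp = laplacian_pinv(g, nodes)
    n = len(nodes)
    out = dict.fromkeys(nodes, 0.0)
    if n < 3:
        return out
    for s, t in itertools.combinations(range(n), 2):
        b = np.zeros(n)
        b[s], b[t] = 1.0, -1.0
        p = lp @ b
        for v in nodes:
            i = idx[v]
            if i in (s, t):
                continue
            flow = sum(abs(p[i] - p[idx[u]]) for u in g.neighbors(v))
            out[v] += 0.5 * flow
    npairs = (n - 1) * (n - 2) / 2
    return {v: x / npairs for v, x in out.items()}


def cf_pair_throughput(g: nx.Graph, s, t) -> dict:
    """Current through each non-endpoint node for a single (s, t) pair."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    lp = laplacian_pinv(g, nodes)
    b = np.zeros(len(nodes))
    b[idx[s]], b[idx[t]] = 1.0, -1.0
    p = lp @ b
    return {
        v: 0.5 * sum(abs(p[idx[v]] - p[idx[u]]) for u in g.neighbors(v))
        for v in nodes if v not in (s, t)
    }


def katz_series_brute(g, alpha: float, kmax: int = 60) -> dict:
    """Truncated sum_{k>=1} alpha^k (A^T)^k 1 (directed graphs allowed)."""
    nodes = sorted(g.nodes)
    at = nx.to_numpy_array(g, nodelist=nodes).T
    x = np.zeros(len(nodes))
    term = np.ones(len(nodes))
    for _ in range(kmax):
        term = alpha * at @ term
        x += term
    return dict(zip(nodes, x))


def eigenvector_brute(g: nx.Graph) -> dict:
    """Principal eigenvector from a full symmetric eigendecomposition."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    vec = np.abs(vec) / np.linalg.norm(vec)
    return dict(zip(nodes, vec))


def pagerank_brute(g, damping: float = 0.85) -> dict:
    """Dense linear solve of the PageRank system with dangling correction."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    n = len(nodes)
    outdeg = a.sum(1)
    p = np.empty((n, n))
    for i in range(n):
        p[i] = a[i] / outdeg[i] if outdeg[i] > 0 else 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * p.T, (1 - damping) / n * np.ones(n))
    return dict(zip(nodes, x / x.sum() * 1.0)) if False else dict(zip(nodes, x))


def degree_brute(g: nx.Graph) -> dict:
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    return dict(zip(nodes, a.sum(1)))


def spearman_formula(rx, ry) -> float:
    """Eq.-style tie-free Spearman: 1 - 6 sum d^2 / (n (n^2-1))."""
    d2 = sum((rx[g] - ry[g]) ** 2 for g in rx)
    n = len(rx)
    return 1 - 6 * d2 / (n * (n * n - 1))


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> nx.Graph:
    """Seeded Erdos–Renyi graph, resampled until connected."""
    while True:
        g = nx.Graph()
        g.add_nodes_from(f"N{i:02d}" for i in range(n))
        nodes = sorted(g.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(nodes[i], nodes[j])
        if nx.is_connected(g):
            return g


def random_tree(rng: np.random.Generator, n: int) -> nx.Graph:
    """Random labelled tree via a seeded Prüfer-like attachment."""
    g = nx.Graph()
    names = [f"T{i:02d}" for i in range(n)]
    g.add_node(names[0])
    for i in range(1, n):
        g.add_edge(names[i], names[int(rng.integers(0, i))])
    return g


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3) -> nx.DiGraph:
    g = nx.DiGraph()
    names = [f"D{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(names[i], names[j])
    return g
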