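"""The ten node-centrality measures used to rank immunome proteins.

Connectivity:   degree (and, for digraphs, in-/out-degree).
Distance:       eccentricity, closeness, centroid value.
Shortest paths: shortest-path (SP) betweenness.
Current flow:   CF-closeness and CF-betweenness, the electrical-network
                measures in which pairwise "distance" is effective
                resistance and "flow" is the current through a node.
Feedback:       Katz status index, eigenvector centrality, PageRank.

All measures are computed here from dense linear algebra / BFS on the
(small) analysis networks.  Distance- and current-flow-based measures are
defined within each connected component; nodes in singleton components
are excluded from those measures with a warning rather than scored with
infinities.

Conventions
-----------
* SP betweenness sums sigma_jk(i)/sigma_jk over unordered pairs {j, k}
  with both endpoints distinct from i; unreachable pairs contribute 0.
* CF measures use the Brandes–Fleischer normalization: CF-closeness is
  (n_c - 1) over the summed effective resistances; CF-betweenness is the
  mean over pairs of the current through the node.
* Katz is the attenuated walk series sum_{k>=1} alpha^k (A^T)^k 1,
  requiring alpha * lambda_max < 1; the spectrally safe default is
  alpha = 0.5 / lambda_max.
* Eigenvector centrality is the principal eigenvector of A (power
  iteration on A + I so bipartite components converge), nonnegative and
  of unit Euclidean norm per component.
* PageRank uses damping d (default 0.85) with uniform teleportation and
  uniform redistribution of dangling mass; scores sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_core import GeneNetwork, connected_components

logger = logging.getLogger(__name__)

UNDIRECTED_MEASURES = (
    "degree",
    "eccentricity",
    "closeness",
    "centroid",
    "sp_betweenness",
    "cf_closeness",
    "cf_betweenness",
    "katz",
    "eigenvector",
    "pagerank",
)

DIRECTED_MEASURES = ("in_degree", "out_degree", "katz", "pagerank")

_POWER_TOL = 1e-12
_POWER_MAXIT = 10_000


@dataclass
class ScoreTable:
    """Finite centrality scores for one measure over the analyzed nodes."""

    measure: str
    scores: dict[str, float]
    note: str = ""

    def __post_init__(self) -> None:
        bad = {g for g, s in self.scores.items() if not np.isfinite(s)}
        if bad:
            raise ValueError(f"{self.measure}: non-finite scores for {sorted(bad)[:5]}")

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.scores[g] for g in order])


@dataclass
class CentralityContext:
    """Cached per-network quantities reused across measures."""

    net: GeneNetwork
    nodes: list[str] = field(init=False)
    A: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = self.net.sorted_nodes()
        self.A = self.net.adjacency(self.nodes)
        self._components: list[list[str]] | None = None
        self._lambda_max: float | None = None
        self._dist_cache: dict[tuple[str, ...], np.ndarray] = {}

    @property
    def components(self) -> list[list[str]]:
        if self._components is None:
            self._components = [sorted(c) for c in connected_components(self.net)]
        return self._components

    @property
    def lambda_max(self) -> float:
        """Spectral radius of the adjacency matrix."""
        if self._lambda_max is None:
            if self.net.directed:
                self._lambda_max = float(np.max(np.abs(np.linalg.eigvals(self.A))))
            else:
                self._lambda_max = float(np.max(np.linalg.eigvalsh(self.A)))
        return self._lambda_max

    def sub_adjacency(self, comp: list[str]) -> np.ndarray:
        return self.net.adjacency(comp)

    def bfs_distances(self, comp: list[str]) -> np.ndarray:
        """All-pairs hop distances inside one component (dense BFS layers)."""
        key = tuple(comp)
        if key in self._dist_cache:
            return self._dist_cache[key]
        a = self.sub_adjacency(comp).astype(bool)
        n = len(comp)
        d = np.full((n, n), -1, dtype=int)
        for s in range(n):
            dist = d[s]
            dist[s] = 0
            frontier = np.zeros(n, dtype=bool)
            frontier[s] = True
            level = 0
            while frontier.any():
                level += 1
                nxt = (a[frontier].any(axis=0)) & (dist < 0)
                dist[nxt] = level
                frontier = nxt
        self._dist_cache[key] = d
        return d


def _context(net_or_ctx) -> CentralityContext:
    if isinstance(net_or_ctx, CentralityContext):
        return net_or_ctx
    return CentralityContext(net_or_ctx)


def _warn_singletons(ctx: CentralityContext, measure: str) -> None:
    single = [c[0] for c in ctx.components if len(c) == 1]
    if single:
        logger.warning(
            "%s: %d singleton node(s) excluded (no finite distances): %s",
            measure, len(single), single[:5],
        )


# ---------------------------------------------------------------------------
# connectivity

def degree_centrality(net) -> ScoreTable:
    """Row sums of the adjacency matrix (undirected edge counts)."""
    ctx = _context(net)
    deg = ctx.A.sum(axis=1)
    return ScoreTable("degree", dict(zip(ctx.nodes, deg.tolist())))


def in_out_degree(net) -> tuple[ScoreTable, ScoreTable]:
    """Arc head / tail counts per node of a digraph."""
    ctx = _context(net)
    if not ctx.net.directed:
        raise ValueError("in/out-degree requires a directed network")
    indeg = ctx.A.sum(axis=0)
    outdeg = ctx.A.sum(axis=1)
    return (
        ScoreTable("in_degree", dict(zip(ctx.nodes, indeg.tolist()))),
        ScoreTable("out_degree", dict(zip(ctx.nodes, outdeg.tolist()))),
    )


# ---------------------------------------------------------------------------
# distance-based (per component)

def eccentricity_centrality(net) -> ScoreTable:
    """1 / (maximum hop distance from the node), within its component."""
    ctx = _context(net)
    _warn_singletons(ctx, "eccentricity")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        if len(comp) < 2:
            continue
        d = ctx.bfs_distances(comp)
        ecc = d.max(axis=1)
        for v, e in zip(comp, ecc):
            scores[v] = 1.0 / float(e)
    return ScoreTable("eccentricity", scores, note="per-component")


def closeness_centrality(net) -> ScoreTable:
    """1 / (sum of hop distances to the node's component co-members)."""
    ctx = _context(net)
    _warn_singletons(ctx, "closeness")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        if len(comp) < 2:
            continue
        d = ctx.bfs_distances(comp)
        tot = d.sum(axis=1)
        for v, t in zip(comp, tot):
            scores[v] = 1.0 / float(t)
    return ScoreTable("closeness", scores, note="per-component")


def centroid_centrality(net) -> ScoreTable:
    """Centroid value: min over competitors j of gamma_i(j) - gamma_j(i).

    gamma_i(j) counts the nodes w (distinct from i and j) strictly closer
    to i than to j; a positive centroid value marks a node that wins the
    "who is nearer to the rest of the network" comparison against every
    competitor.
    """
    ctx = _context(net)
    _warn_singletons(ctx, "centroid")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        n = len(comp)
        if n < 2:
            continue
        d = ctx.bfs_distances(comp)
        f = np.zeros((n, n))
        for i in range(n):
            closer_i = d[:, i][:, None] < d  # w closer to i than to column j
            gamma_i = closer_i.sum(axis=0)
            # remove w = i (d(i,i)=0 < d(i,j) always counts) and w = j (never counts)
            gamma_i = gamma_i - (d[i, :] > 0)
            f[i, :] = gamma_i
        fmat = f - f.T
        np.fill_diagonal(fmat, np.inf)
        vals = fmat.min(axis=1)
        for v, s in zip(comp, vals):
            scores[v] = float(s)
    return ScoreTable("centroid", scores, note="per-component")


# ---------------------------------------------------------------------------
# shortest-path betweenness (Brandes accumulation)

def sp_betweenness(net) -> ScoreTable:
    """Sum over unordered pairs {j,k} of the fraction of j-k shortest paths
    through the node (endpoints excluded); unreachable pairs contribute 0."""
    ctx = _context(net)
    n = len(ctx.nodes)
    a = ctx.A.astype(bool)
    bc = np.zeros(n)
    adj = [np.flatnonzero(a[i]) for i in range(n)]
    for s in range(n):
        # single-source shortest-path counts (BFS), then dependency accumulation
        dist = np.full(n, -1)
        sigma = np.zeros(n)
        dist[s] = 0
        sigma[s] = 1.0
        order: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                order.append(v)
                for w in adj[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair visited from both endpoints
    return ScoreTable("sp_betweenness", dict(zip(ctx.nodes, bc.tolist())))


# ---------------------------------------------------------------------------
# current flow (per component, Laplacian pseudoinverse)

def _laplacian_pinv(a: np.ndarray) -> np.ndarray:
    lap = np.diag(a.sum(axis=1)) - a
    return np.linalg.pinv(lap)


def cf_closeness(net) -> ScoreTable:
    """Current-flow (information) closeness: (n_c - 1) over the summed
    effective resistances from the node to its component co-members."""
    ctx = _context(net)
    _warn_singletons(ctx, "cf_closeness")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        n = len(comp)
        if n < 2:
            continue
        lp = _laplacian_pinv(ctx.sub_adjacency(comp))
        diag = np.diag(lp)
        # R_eff(i, j) = lp_ii + lp_jj - 2 lp_ij
        r = diag[:, None] + diag[None, :] - 2 * lp
        tot = r.sum(axis=1)  # diagonal contributes 0
        for v, t in zip(comp, tot):
            scores[v] = (n - 1) / float(t)
    return ScoreTable("cf_closeness", scores, note="per-component")


def cf_betweenness(net) -> ScoreTable:
    """Mean over pairs {j,k} of the current through the node when a unit
    current is sent from j to k.

    The throughput of node i for pair (j, k) is half the summed absolute
    currents on i's incident edges; pairs with i as an endpoint are
    excluded, and the sum over pairs is divided by (n_c-1)(n_c-2)/2.
    For every edge the full pairwise sum of |potential differences| is
    obtained from the sorted potential-difference vector in O(n log n).
    """
    ctx = _context(net)
    _warn_singletons(ctx, "cf_betweenness")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        n = len(comp)
        if n < 2:
            continue
        if n == 2:
            scores[comp[0]] = 0.0
            scores[comp[1]] = 0.0
            continue
        idx = {v: i for i, v in enumerate(comp)}
        lp = _laplacian_pinv(ctx.sub_adjacency(comp))
        acc = np.zeros(n)
        comp_set = set(comp)
        edges = [
            (idx[u], idx[v])
            for u, v in ctx.net.edges
            if u in comp_set and v in comp_set
        ]
        for u, v in edges:
            c = lp[u] - lp[v]  # current on edge (u,v) for pair (s,t) is c[s]-c[t]
            srt = np.sort(c)
            coef = 2 * np.arange(n) - (n - 1)
            full = float(coef @ srt)  # sum_{s<t} |c_s - c_t|
            for w in (u, v):
                involving_w = float(np.abs(c - c[w]).sum())
                acc[w] += 0.5 * (full - involving_w)
        npairs = (n - 1) * (n - 2) / 2
        for v, s in zip(comp, acc / npairs):
            scores[v] = float(s)
    return ScoreTable("cf_betweenness", scores, note="per-component")


# ---------------------------------------------------------------------------
# feedback

def katz_centrality(net, alpha: float | None = None) -> ScoreTable:
    """Katz status index: attenuated count of all walks into the node.

    score = sum_{k>=1} alpha^k (A^T)^k 1, computed by solving
    (I - alpha A^T) x = alpha A^T 1.  Requires alpha < 1/lambda_max.
    """
    ctx = _context(net)
    lam = ctx.lambda_max
    if alpha is None:
        alpha = 0.5 / lam if lam > 0 else 0.5
    if lam > 0 and alpha >= 1.0 / lam:
        raise ValueError(
            f"katz: alpha={alpha:.6g} >= 1/lambda_max={1.0 / lam:.6g}; "
            "the walk series diverges"
        )
    n = len(ctx.nodes)
    at = ctx.A.T
    rhs = alpha * at @ np.ones(n)
    x = np.linalg.solve(np.eye(n) - alpha * at, rhs)
    return ScoreTable("katz", dict(zip(ctx.nodes, x.tolist())), note=f"alpha={alpha:.6g}")


def eigenvector_centrality(net) -> ScoreTable:
    """Principal adjacency eigenvector, nonnegative, unit L2 norm.

    Computed per connected component by power iteration on A + I (the
    shift leaves eigenvectors unchanged and guarantees convergence on
    bipartite components); tolerance 1e-12 on the max score change.
    """
    ctx = _context(net)
    if ctx.net.directed:
        raise ValueError("eigenvector centrality is defined here for undirected networks")
    scores: dict[str, float] = {}
    for comp in ctx.components:
        n = len(comp)
        if n == 1:
            scores[comp[0]] = 1.0
            continue
        a = ctx.sub_adjacency(comp)
        x = np.full(n, 1.0 / np.sqrt(n))
        for it in range(_POWER_MAXIT):
            y = a @ x + x
            y /= np.linalg.norm(y)
            if np.abs(y - x).max() < _POWER_TOL:
                x = y
                break
            x = y
        else:
            raise RuntimeError(
                f"eigenvector centrality did not converge in {_POWER_MAXIT} iterations"
            )
        x = np.abs(x)
        for v, s in zip(comp, x):
            scores[v] = float(s)
    return ScoreTable("eigenvector", scores, note="per-component, unit L2 norm")


def pagerank_centrality(net, damping: float = 0.85) -> ScoreTable:
    """PageRank: stationary distribution of the damped random walk.

    Dangling nodes redistribute their mass uniformly; teleportation is
    uniform; power iteration to 1e-12 L1 change.  Scores sum to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must lie in (0, 1), got {damping}")
    ctx = _context(net)
    n = len(ctx.nodes)
    a = ctx.A
    outdeg = a.sum(axis=1)
    dangling = outdeg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(outdeg[:, None] > 0, a / np.where(outdeg == 0, 1, outdeg)[:, None], 0.0)
    x = np.full(n, 1.0 / n)
    tele = (1.0 - damping) / n
    for it in range(_POWER_MAXIT):
        y = damping * (p.T @ x) + damping * x[dangling].sum() / n + tele
        if np.abs(y - x).sum() < _POWER_TOL:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"pagerank did not converge in {_POWER_MAXIT} iterations")
    return ScoreTable("pagerank", dict(zip(ctx.nodes, x.tolist())), note=f"d={damping}")


# ---------------------------------------------------------------------------
# batteries

def undirected_measures(net, alpha: float | None = None, damping: float = 0.85,
                        ) -> dict[str, ScoreTable]:
    """All ten measures for an undirected network, keyed by measure name."""
    ctx = _context(net)
    if ctx.net.directed:
        raise ValueError("undirected_measures requires an undirected network")
    return {
        "degree": degree_centrality(ctx),
        "eccentricity": eccentricity_centrality(ctx),
        "closeness": closeness_centrality(ctx),
        "centroid": centroid_centrality(ctx),
        "sp_betweenness": sp_betweenness(ctx),
        "cf_closeness": cf_closeness(ctx),
        "cf_betweenness": cf_betweenness(ctx),
        "katz": katz_centrality(ctx, alpha=alpha),
        "eigenvector": eigenvector_centrality(ctx),
        "pagerank": pagerank_centrality(ctx, damping=damping),
    }


def directed_measures(net, alpha: float | None = None, damping: float = 0.85,
                      ) -> dict[str, ScoreTable]:
    """The four measures computable on the sparse signaling digraph."""
    ctx = _context(net)
    if not ctx.net.directed:
        raise ValueError("directed_measures requires a directed network")
    indeg, outdeg = in_out_degree(ctx)
    return {
        "in_degree": indeg,
        "out_degree": outdeg,
        "katz": katz_centrality(ctx, alpha=alpha),
        "pagerank": pagerank_centrality(ctx, damping=damping),
    }
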