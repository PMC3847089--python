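"""Construction of the analysis networks from flat-file inputs.

Covers the four steps that turn an interactome export and curated gene
lists into the network actually analyzed: parsing tab-separated edge
lists (optionally signed), parsing one-symbol-per-line gene lists,
inducing the subnetwork on a gene list, dropping orphan (degree-0)
nodes, and orienting signed signaling edges into a digraph.

Gene identity is the upper-cased, whitespace-trimmed symbol string; no
identifier mapping is attempted.  Duplicate edges and self-loops — both
present in real interactome exports — are dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .graph_core import SIGN_CODES, GeneNetwork, _norm_edge

logger = logging.getLogger(__name__)

# inhibition arrives as a variety of dashes in the wild
_SIGN_ALIASES = {"+": "+", "-": "-", "−": "-", "0": "0"}


def _norm_symbol(s: str) -> str:
    return s.strip().upper()


def read_edge_list(path, signed: bool = False) -> GeneNetwork:
    """Parse a 2- (or, if ``signed``, 3-) column TSV edge list.

    Lines starting with ``#`` are comments.  Duplicates and self-loops are
    collapsed/dropped with a logged count; malformed lines raise with their
    line number.
    """
    path = Path(path)
    want = 3 if signed else 2
    edges: set = set()
    signs: dict = {}
    extra_codes: dict = {}  # edge -> set of conflicting duplicate sign codes
    nodes: set[str] = set()
    n_dup = n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != want:
                raise ValueError(
                    f"{path}:{lineno}: expected {want} tab-separated columns, "
                    f"got {len(parts)}"
                )
            a, b = _norm_symbol(parts[0]), _norm_symbol(parts[1])
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            if a == b:
                n_self += 1
                continue
            nodes.update((a, b))
            e = _norm_edge(a, b, directed=False)
            if signed:
                code = _SIGN_ALIASES.get(parts[2].strip())
                if code is None:
                    raise ValueError(
                        f"{path}:{lineno}: unknown sign code {parts[2].strip()!r} "
                        f"(expected one of {SIGN_CODES})"
                    )
                if e in edges:
                    n_dup += 1
                    if signs.get(e) != code:
                        # conflicting records: keep the arcs implied by both
                        logger.warning(
                            "%s:%d: conflicting sign %r for edge %s (already %r); "
                            "keeping the arcs of both records",
                            path, lineno, code, e, signs.get(e),
                        )
                        extra_codes.setdefault(e, set()).add(code)
                    continue
                signs[e] = code
            elif e in edges:
                n_dup += 1
                continue
            edges.add(e)
    if n_dup or n_self:
        logger.info(
            "%s: dropped %d duplicate edges and %d self-loops", path, n_dup, n_self
        )
    net = GeneNetwork(nodes=nodes, edges=edges, directed=False,
                      signs=signs if signed else None)
    if extra_codes:
        net.extra_sign_codes = extra_codes  # consulted by orient_signaling
    return net


def read_gene_list(path) -> set[str]:
    """One symbol per line; blank lines ignored; normalized and deduplicated."""
    path = Path(path)
    genes = {
        _norm_symbol(line)
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }
    if not genes:
        raise ValueError(f"{path}: no gene symbols found")
    return genes


def induce_subnetwork(ppi: GeneNetwork, genes: set[str]) -> GeneNetwork:
    """Subnetwork on ``genes``: their edges, plus listed genes kept isolated.

    Genes absent from the interactome stay as isolated nodes so that the
    subsequent orphan-removal step mirrors the published procedure; an empty
    intersection with the interactome is an error.
    """
    if not genes:
        raise ValueError("empty gene list")
    genes = {_norm_symbol(g) for g in genes}
    if not (genes & ppi.nodes):
        raise ValueError("gene list shares no genes with the interaction network")
    edges = {e for e in ppi.edges if e[0] in genes and e[1] in genes}
    signs = None
    if ppi.signs is not None:
        signs = {e: s for e, s in ppi.signs.items() if e in edges}
    net = GeneNetwork(nodes=set(genes), edges=edges, directed=ppi.directed, signs=signs)
    if getattr(ppi, "extra_sign_codes", None):
        net.extra_sign_codes = {
            e: c for e, c in ppi.extra_sign_codes.items() if e in edges
        }
    return net


def remove_orphans(net: GeneNetwork) -> GeneNetwork:
    """Drop degree-0 nodes; the edge set is unchanged."""
    deg = net.degree()
    keep = {v for v, d in deg.items() if d > 0}
    dropped = net.n_nodes - len(keep)
    if dropped:
        logger.info("removed %d orphan nodes", dropped)
    out = GeneNetwork(nodes=keep, edges=set(net.edges), directed=net.directed,
                      signs=dict(net.signs) if net.signs is not None else None)
    if getattr(net, "extra_sign_codes", None):
        out.extra_sign_codes = dict(net.extra_sign_codes)
    return out


def orient_signaling(signed_net: GeneNetwork) -> GeneNetwork:
    """Turn a signed undirected network into a signaling digraph.

    For a record (A, B, sign) with A < B lexicographically as stored:
    activation ``+`` gives the arc A->B, inhibition ``-`` gives B->A
    (signal flows from the inhibited protein back to its regulator), and
    physical interaction ``0`` gives both arcs.
    """
    if signed_net.signs is None:
        raise ValueError("network carries no sign codes")
    missing = signed_net.edges - set(signed_net.signs)
    if missing:
        raise ValueError(f"{len(missing)} edges missing a sign code")
    arcs: set[tuple[str, str]] = set()

    def add(a: str, b: str, code: str) -> None:
        if code == "+":
            arcs.add((a, b))
        elif code == "-":
            arcs.add((b, a))
        else:
            arcs.add((a, b))
            arcs.add((b, a))

    for (a, b), code in signed_net.signs.items():
        add(a, b, code)
    for (a, b), codes in getattr(signed_net, "extra_sign_codes", {}).items():
        for code in codes:
            add(a, b, code)
    return GeneNetwork(nodes=set(signed_net.nodes), edges=arcs, directed=True)
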