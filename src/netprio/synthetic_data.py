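"""Seeded generators emulating the study's inputs.

Real inputs of this kind of analysis — an interactome export, a curated
immunome gene list, a known-disease gene list and GO annotations — are
moving database snapshots.  This module fabricates a self-consistent
replacement world at desk scale so that every pipeline stage runs and
can be validated end to end:

* a connected preferential-attachment (Barabási–Albert) network of
  ~550 synthetic gene symbols, matching the published network's scale
  (hundreds of nodes, mean degree ~5, heavy-tailed degrees);
* a signed variant of the same network with activation/inhibition/
  physical interaction codes for the directed analysis;
* a planted set of disease genes drawn from the top degree quartile,
  of which a designated "hidden" subset is withheld from the known
  list — the pipeline should rediscover exactly these;
* GO-style annotations per namespace, including a block of disease
  terms whose gene content is biased toward the planted disease genes,
  emitted as valid GAF 2.2 plus a minimal OBO ontology.

All generators are pure functions of the config (seed included): the
same config yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_core import GeneNetwork

NS_PREFIX = {"BP": 1, "MF": 2, "CC": 3}


@dataclass
class SyntheticConfig:
    seed: int = 1
    n_nodes: int = 550
    attachment_m: int = 3          # BA attachment; targets mean degree ~ 2m
    n_phantom_genes: int = 10      # listed genes absent from the interactome
    n_terms: int = 60              # background terms per namespace
    term_size_range: tuple[int, int] = (2, 60)  # straddles the 3..50 filter
    n_disease_terms: int = 4       # per namespace
    disease_term_size_range: tuple[int, int] = (14, 20)
    disease_weight: float = 1000.0  # sampling weight of planted genes in disease terms
    hidden_term_copies: int = 2    # disease terms per namespace holding each hidden gene
    n_known_genes: int = 50
    n_planted_candidates: int = 8
    hidden_pool_size: int = 50     # hidden genes drawn from this top-degree slice
    sign_fracs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # +, -, 0

    def __post_init__(self) -> None:
        if self.n_planted_candidates >= self.n_known_genes:
            raise ValueError("need fewer planted candidates than known genes")
        lo, hi = self.term_size_range
        if not (2 <= lo and hi <= 60):
            raise ValueError("term sizes must lie within [2, 60]")
        if abs(sum(self.sign_fracs) - 1.0) > 1e-9:
            raise ValueError("sign fractions must sum to 1")


def _symbol(i: int) -> str:
    return f"G{i + 1:04d}"


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_network(cfg: SyntheticConfig) -> GeneNetwork:
    """Connected BA preferential-attachment graph over synthetic symbols."""
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment_m, seed=cfg.seed)
    edges = {(_symbol(u), _symbol(v)) for u, v in g.edges()}
    nodes = {_symbol(v) for v in g.nodes()}
    return GeneNetwork.from_edges(edges, directed=False, extra_nodes=nodes)


def generate_signed_edges(net: GeneNetwork, cfg: SyntheticConfig) -> GeneNetwork:
    """Assign each edge a seeded sign code: + activation, - inhibition,
    0 physical interaction."""
    rng = _rng(cfg, 1)
    edges = sorted(net.edges)
    codes = rng.choice(["+", "-", "0"], size=len(edges), p=list(cfg.sign_fracs))
    signs = dict(zip(edges, codes.tolist()))
    return GeneNetwork(nodes=set(net.nodes), edges=set(edges), directed=False,
                       signs=signs)


def _degree_order(net: GeneNetwork) -> list[str]:
    deg = net.degree()
    return sorted(net.nodes, key=lambda v: (-deg[v], v))


def plant_disease_genes(net: GeneNetwork, cfg: SyntheticConfig,
                        ) -> tuple[set[str], set[str]]:
    """Choose the known disease genes and the hidden candidate genes.

    Both sets come from the top degree quartile, mirroring the observed
    concentration of known disease genes among network hubs.  Hidden
    candidates are drawn from the very top of the degree ranking (the
    ``hidden_pool_size`` highest-degree genes) so that, once withheld
    from the known list, they are guaranteed to sit in the pooled
    high-score set the pipeline builds; known genes are sampled from the
    rest of the quartile with degree-proportional weights.
    """
    order = _degree_order(net)
    quartile = order[: int(np.ceil(net.n_nodes / 4))]
    if cfg.n_known_genes + cfg.n_planted_candidates > len(quartile):
        raise ValueError(
            f"{cfg.n_known_genes} known + {cfg.n_planted_candidates} hidden genes "
            f"exceed the top-quartile size {len(quartile)}"
        )
    rng = _rng(cfg, 2)
    pool_hidden = quartile[: min(cfg.hidden_pool_size, len(quartile))]
    hidden = {str(g) for g in rng.choice(pool_hidden, cfg.n_planted_candidates, replace=False)}
    deg = net.degree()
    rest = [v for v in quartile if v not in hidden]
    w = np.array([deg[v] for v in rest], dtype=float)
    known = {str(g) for g in rng.choice(rest, cfg.n_known_genes, replace=False, p=w / w.sum())}
    assert not known & hidden
    return known, hidden


def _term_id(ns: str, i: int) -> str:
    return f"GO:{NS_PREFIX[ns]}{i:06d}"


def generate_annotations(net: GeneNetwork, cfg: SyntheticConfig,
                         known: set[str], hidden: set[str],
                         ) -> tuple[dict, dict, dict]:
    """Per-namespace annotations with a planted-enrichment disease block.

    Returns (term2genes per namespace, is_a parent links, disease term ids).
    Background terms sample genes uniformly; the first two background
    terms per namespace are pinned to sizes 2 and 60 so the 3..50 term
    filter is exercised on both flanks.  Disease terms carry every hidden
    gene (round-robin, ``hidden_term_copies`` terms each) and fill their
    remaining slots by weighted sampling that favours planted disease
    genes by ``disease_weight`` to 1.
    """
    from .go_enrichment import NAMESPACES

    genes = sorted(net.nodes)
    planted = sorted(known | hidden)
    planted_set = set(planted)
    terms: dict[str, dict[str, set[str]]] = {}
    parents: dict[str, str] = {}
    disease_ids: dict[str, list[str]] = {}
    hidden_sorted = sorted(hidden)
    for ns_i, ns in enumerate(NAMESPACES):
        rng = _rng(cfg, 10 + ns_i)
        t2g: dict[str, set[str]] = {}
        root = _term_id(ns, 900000)
        mid = _term_id(ns, 900001)
        parents[mid] = root
        lo, hi = cfg.term_size_range
        for i in range(cfg.n_terms):
            tid = _term_id(ns, i + 1)
            size = 2 if i == 0 else (hi if i == 1 else int(rng.integers(lo, hi + 1)))
            t2g[tid] = {str(g) for g in rng.choice(genes, size, replace=False)}
            parents[tid] = mid if i < 10 else root
        dlo, dhi = cfg.disease_term_size_range
        disease_ids[ns] = []
        for j in range(cfg.n_disease_terms):
            tid = _term_id(ns, 500000 + j)
            disease_ids[ns].append(tid)
            forced = {
                hidden_sorted[h]
                for h in range(len(hidden_sorted))
                for c in range(cfg.hidden_term_copies)
                if (h * cfg.hidden_term_copies + c) % cfg.n_disease_terms == j
            }
            size = int(rng.integers(dlo, dhi + 1))
            remaining = [g for g in genes if g not in forced]
            w = np.array([cfg.disease_weight if g in planted_set else 1.0
                          for g in remaining])
            extra = rng.choice(remaining, max(0, size - len(forced)),
                               replace=False, p=w / w.sum())
            t2g[tid] = forced | {str(g) for g in extra}
            parents[tid] = root
        terms[ns] = t2g
    return terms, parents, disease_ids


def write_gaf(terms: dict, path) -> None:
    """Emit the annotations as GAF 2.2 (17 columns, deterministic order)."""
    aspect = {"BP": "P", "MF": "F", "CC": "C"}
    lines = ["!gaf-version: 2.2"]
    for ns in sorted(terms):
        for tid in sorted(terms[ns]):
            for g in sorted(terms[ns][tid]):
                cols = [
                    "NETPRIO", g, g, "involved_in", tid, "NP_REF:0000001",
                    "IEA", "", aspect[ns], "", "", "protein",
                    "taxon:9606", "20130101", "NETPRIO", "", "",
                ]
                lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_obo(terms: dict, parents: dict[str, str], path) -> None:
    """Emit a minimal OBO 1.2 ontology with the generated is_a links."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function",
               "CC": "cellular_component"}
    out = ["format-version: 1.2", "ontology: netprio-synthetic", ""]
    seen: set[str] = set()

    def stanza(tid: str, ns: str) -> None:
        if tid in seen:
            return
        seen.add(tid)
        out.extend([
            "[Term]", f"id: {tid}", f"name: synthetic term {tid}",
            f"namespace: {ns_long[ns]}",
        ])
        if tid in parents:
            out.append(f"is_a: {parents[tid]} ! parent")
        out.append("")

    for ns in sorted(terms):
        roots = {p for t, p in parents.items() if t in terms[ns]}
        for r in sorted(roots | {p for p in parents.values()}):
            if r.startswith(f"GO:{NS_PREFIX[ns]}"):
                stanza(r, ns)
        for tid in sorted(terms[ns]):
            stanza(tid, ns)
    Path(path).write_text("\n".join(out) + "\n")


def write_bundle(cfg: SyntheticConfig, outdir) -> dict:
    """Generate and write the complete input bundle for the pipeline.

    Files: interactome edge list (TSV), signed edge list, immunome-style
    gene list (network genes plus phantom symbols absent from the
    interactome), known-disease gene list, GAF 2.2 annotations, OBO
    ontology, and a ground-truth JSON naming the hidden candidates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(cfg)
    signed = generate_signed_edges(net, cfg)
    known, hidden = plant_disease_genes(net, cfg)
    terms, parents, disease_ids = generate_annotations(net, cfg, known, hidden)

    edges = sorted(net.edges)
    (outdir / "ppi_edges.tsv").write_text(
        "# synthetic interactome edge list\n"
        + "\n".join(f"{a}\t{b}" for a, b in edges) + "\n")
    (outdir / "signed_edges.tsv").write_text(
        "# synthetic signed signaling edge list\n"
        + "\n".join(f"{a}\t{b}\t{signed.signs[(a, b)]}" for a, b in edges) + "\n")
    phantoms = [f"GX{i + 1:04d}" for i in range(cfg.n_phantom_genes)]
    (outdir / "immunome_genes.txt").write_text(
        "\n".join(sorted(net.nodes) + phantoms) + "\n")
    (outdir / "known_genes.txt").write_text("\n".join(sorted(known)) + "\n")
    write_gaf(terms, outdir / "annotations.gaf")
    write_obo(terms, parents, outdir / "ontology.obo")
    truth = {
        "seed": cfg.seed,
        "hidden_candidates": sorted(hidden),
        "known_genes": sorted(known),
        "disease_terms": {ns: sorted(ids) for ns, ids in disease_ids.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
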