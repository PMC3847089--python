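"""GO annotation ingestion and hypergeometric term enrichment.

The enrichment model is the classic target-versus-background urn: with a
background (source) of N network genes of which B are annotated to a
term, and a target of n known disease genes of which b are annotated,
the term's p-value is the upper hypergeometric tail

    p = P(X >= b),   X ~ Hypergeometric(N, B, n).

Terms are pre-filtered by annotation count within the background (the
published procedure keeps terms annotating at least 3 but at most 50
network genes) and a raw p < 0.001 threshold is applied per namespace;
no multiple-testing correction is used by default (an optional
Benjamini–Hochberg flag is provided).  The genes of the significant
terms, within the background, form the "significant disease ontologies"
gene set consumed by the candidate prediction step.

Annotation input is GAF 2.x; an optional OBO ontology enables true-path
propagation of annotations along is_a links.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import networkx as nx
import obonet
from scipy import stats

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC")
_ASPECT_TO_NS = {"P": "BP", "F": "MF", "C": "CC"}
_OBO_NS = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_TERM_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationSet:
    """Bidirectional gene <-> GO-term mapping for one namespace."""

    namespace: str
    gene2terms: dict[str, set[str]] = field(default_factory=dict)
    term2genes: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, term: str) -> None:
        if not _TERM_RE.match(term):
            raise ValueError(f"bad GO term id {term!r}")
        self.gene2terms.setdefault(gene, set()).add(term)
        self.term2genes.setdefault(term, set()).add(gene)

    def genes_of(self, term: str) -> set[str]:
        return set(self.term2genes.get(term, set()))

    def terms_of(self, gene: str) -> set[str]:
        return set(self.gene2terms.get(gene, set()))

    @property
    def n_annotations(self) -> int:
        return sum(len(t) for t in self.gene2terms.values())

    def check_consistency(self) -> None:
        fwd = {(g, t) for g, ts in self.gene2terms.items() for t in ts}
        rev = {(g, t) for t, gs in self.term2genes.items() for g in gs}
        if fwd != rev:
            raise AssertionError("gene->term and term->gene maps disagree")


@dataclass
class EnrichmentResult:
    """One term's enrichment outcome against the background."""

    term: str
    namespace: str
    N: int  # background size
    B: int  # background genes annotated to term
    n: int  # target size
    b: int  # target genes annotated to term
    p_value: float
    genes: tuple[str, ...]  # the b target hits, sorted

    def __post_init__(self) -> None:
        if not (self.b <= min(self.n, self.B) <= self.N):
            raise ValueError(f"{self.term}: inconsistent counts "
                             f"N={self.N} B={self.B} n={self.n} b={self.b}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.term}: p-value {self.p_value} out of (0, 1]")


def read_gaf(path) -> dict[str, AnnotationSet]:
    """Parse a GAF 2.x file into one AnnotationSet per namespace.

    Uses column 3 (symbol), 4 (qualifier: rows with NOT are dropped),
    5 (term) and 9 (aspect P/F/C); "!"-comment lines are skipped and
    malformed rows are skipped with a warning.
    """
    path = Path(path)
    sets = {ns: AnnotationSet(ns) for ns in NAMESPACES}
    n_rows = n_bad = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                logger.warning("%s:%d: %d columns (<15), row skipped", path, lineno, len(cols))
                n_bad += 1
                continue
            symbol = cols[2].strip().upper()
            qualifier = cols[3]
            term = cols[4].strip()
            aspect = cols[8].strip()
            ns = _ASPECT_TO_NS.get(aspect)
            if not symbol or ns is None or not _TERM_RE.match(term):
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                n_bad += 1
                continue
            if "NOT" in qualifier.split("|"):
                continue
            sets[ns].add(symbol, term)
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no usable annotation rows")
    logger.info("%s: %d annotations loaded, %d malformed rows skipped", path, n_rows, n_bad)
    return sets


def read_obo_ancestors(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """is_a ancestor sets and namespaces for every term of an OBO file."""
    g = obonet.read_obo(path)
    isa = nx.DiGraph()
    isa.add_nodes_from(g.nodes)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            isa.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(isa):
        raise ValueError(f"{path}: is_a graph contains a cycle")
    ns = {
        t: _OBO_NS.get(data.get("namespace", ""), None)
        for t, data in g.nodes(data=True)
    }
    ancestors = {t: set(nx.descendants(isa, t)) for t in isa.nodes}
    return ancestors, ns


def propagate_annotations(annset: AnnotationSet, obo_path) -> AnnotationSet:
    """Apply the true-path rule: annotate each gene to all is_a ancestors
    of its terms, within the annotation set's namespace."""
    ancestors, ns = read_obo_ancestors(obo_path)
    out = AnnotationSet(annset.namespace)
    for gene, terms in annset.gene2terms.items():
        closure = set(terms)
        for t in terms:
            closure |= {
                a for a in ancestors.get(t, set())
                if ns.get(a) in (annset.namespace, None)
            }
        for t in closure:
            out.add(gene, t)
    return out


def filter_terms(annset: AnnotationSet, universe: set[str],
                 min_genes: int = 3, max_genes: int = 50) -> set[str]:
    """Terms annotating between min_genes and max_genes universe genes."""
    if not universe:
        raise ValueError("empty universe")
    return {
        t for t, gs in annset.term2genes.items()
        if min_genes <= len(gs & universe) <= max_genes
    }


def hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """Upper tail P(X >= b) for X ~ Hypergeometric(N, B, n)."""
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def hypergeom_tail_exact(N: int, B: int, n: int, b: int):
    """Exact rational tail sum C(B,i) C(N-B,n-i) / C(N,n) for i >= b."""
    from fractions import Fraction
    total = comb(N, n)
    acc = sum(comb(B, i) * comb(N - B, n - i) for i in range(b, min(B, n) + 1))
    return Fraction(acc, total)


def enrich(target: set[str], universe: set[str], annset: AnnotationSet,
           terms: set[str] | None = None, p_threshold: float = 0.001,
           bh_correct: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric target-vs-background enrichment for a term set.

    Returns the terms with p (or BH-adjusted p, if requested) strictly
    below the threshold, sorted by ascending p then term id.
    """
    if not target <= universe:
        raise ValueError(
            f"{len(target - universe)} target genes are not in the background universe"
        )
    if terms is None:
        terms = set(annset.term2genes)
    N, n = len(universe), len(target)
    results = []
    for term in sorted(terms):
        hits = annset.genes_of(term) & universe
        B = len(hits)
        target_hits = hits & target
        b = len(target_hits)
        p = hypergeom_tail(N, B, n, b)
        results.append(EnrichmentResult(
            term=term, namespace=annset.namespace, N=N, B=B, n=n, b=b,
            p_value=p, genes=tuple(sorted(target_hits)),
        ))
    results.sort(key=lambda r: (r.p_value, r.term))
    if bh_correct:
        m = len(results)
        adj = 1.0
        adjusted = [0.0] * m
        for i in range(m - 1, -1, -1):
            adj = min(adj, results[i].p_value * m / (i + 1))
            adjusted[i] = adj
        return [r for r, q in zip(results, adjusted) if q < p_threshold]
    return [r for r in results if r.p_value < p_threshold]


def genes_of_significant_terms(results, annset: AnnotationSet,
                               universe: set[str]) -> set[str]:
    """Union over significant terms of their annotated universe genes."""
    out: set[str] = set()
    for r in results:
        out |= annset.genes_of(r.term) & universe
    return out
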