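"""End-to-end orchestration of the prioritization analysis.

Given the five inputs — an interactome edge list, the gene list defining
the subnetwork, the known disease gene list, GAF annotations and an
optional OBO ontology — the pipeline:

1. builds the core network (induce on the gene list, drop orphans; in
   directed mode, orient the signed edges into a signaling digraph);
2. reports its topology (mean degree, diameter, clustering, degree
   exponent);
3. computes the centrality measures (all ten, or in-degree/out-degree/
   Katz/PageRank in directed mode), ranks them and writes the Spearman
   cross-measure correlation matrix;
4. pools the per-measure top-k genes (set A), restricts the known list
   to the network (set B) and collects genes of significantly enriched
   GO terms per namespace (set C);
5. applies the Venn prediction rule candidates = (A & C) - B.

Every output is a deterministic TSV/JSON file; the run log records all
parameter values and dropped-record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import candidate_predict, centrality, go_enrichment, network_build, rank_stats
from .graph_core import GeneNetwork, topology_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ppi_path: str
    gene_list_path: str
    known_genes_path: str
    gaf_path: str
    obo_path: str | None = None
    mode: str = "undirected"
    k: int = 50
    p_threshold: float = 0.001
    min_term: int = 3
    max_term: int = 50
    damping: float = 0.85
    alpha: float | None = None          # None -> 0.5 / lambda_max
    propagate: bool = True
    bh_correct: bool = False
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        if self.mode not in ("undirected", "directed"):
            raise ValueError(f"mode must be undirected or directed, got {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p threshold must lie in (0, 1]")
        if not 0 < self.min_term <= self.max_term:
            raise ValueError("need 0 < min_term <= max_term")
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    network: GeneNetwork
    topology: object
    scores: dict[str, centrality.ScoreTable]
    rank_tables: dict[str, rank_stats.RankTable]
    correlation: pd.DataFrame
    top_sets: dict[str, set[str]]
    pooled: set[str]
    known_in_network: set[str]
    enrichment: dict[str, list[go_enrichment.EnrichmentResult]]
    ontology_genes: set[str]
    report: candidate_predict.CandidateReport
    coverage: dict[str, int]
    log: dict = field(default_factory=dict)


def _check_inputs(cfg: PipelineConfig) -> None:
    paths = [cfg.ppi_path, cfg.gene_list_path, cfg.known_genes_path, cfg.gaf_path]
    if cfg.obo_path:
        paths.append(cfg.obo_path)
    missing = [p for p in paths if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    _check_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": {k: v for k, v in asdict(cfg).items()}}

    # --- network construction -------------------------------------------
    signed = cfg.mode == "directed"
    ppi = network_build.read_edge_list(cfg.ppi_path, signed=signed)
    genes = network_build.read_gene_list(cfg.gene_list_path)
    sub = network_build.induce_subnetwork(ppi, genes)
    core = network_build.remove_orphans(sub)
    log["n_listed_genes"] = len(genes)
    log["n_orphans_removed"] = sub.n_nodes - core.n_nodes
    net = network_build.orient_signaling(core) if signed else core
    log["n_nodes"] = net.n_nodes
    log["n_edges"] = net.n_edges

    topo = topology_summary(net)
    (outdir / "topology.json").write_text(json.dumps({
        "n_nodes": net.n_nodes, "n_edges": net.n_edges,
        "average_degree": topo.average_degree, "diameter": topo.diameter,
        "avg_clustering": topo.avg_clustering,
        "degree_exponent": topo.degree_exponent,
        "n_components": topo.n_components,
        "component_diameters": topo.component_diameters,
    }, indent=2) + "\n")

    # --- centrality, ranks, correlation ---------------------------------
    if signed:
        scores = centrality.directed_measures(net, alpha=cfg.alpha, damping=cfg.damping)
    else:
        scores = centrality.undirected_measures(net, alpha=cfg.alpha, damping=cfg.damping)

    rank_tables = {m: rank_stats.rank_scores(t, "average") for m, t in scores.items()}
    corr = rank_stats.correlation_matrix(rank_tables)
    corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t")

    wide = {}
    for m, table in scores.items():
        comp = rank_stats.rank_scores(table, "competition")
        df = pd.DataFrame({
            "gene": sorted(table.scores),
            "measure": m,
            "score": [table.scores[g] for g in sorted(table.scores)],
            "rank": [comp.ranks[g] for g in sorted(table.scores)],
        }).sort_values(["rank", "gene"])
        df.to_csv(outdir / f"scores_{m}.tsv", sep="\t", index=False)
        wide[m] = pd.Series(table.scores)
    pd.DataFrame(wide).rename_axis("gene").to_csv(outdir / "scores_matrix.tsv", sep="\t")

    top_sets = {m: rank_stats.top_k_genes(t, cfg.k) for m, t in scores.items()}
    pooled = rank_stats.pool_top_genes(top_sets.values())
    log["top_k"] = cfg.k
    log["pooled_high_score_genes"] = len(pooled)
    log["pooled_truncated"] = len(set().union(
        *(set(sorted(t.scores, key=lambda g: (-t.scores[g], g))[: cfg.k])
          for t in scores.values())))

    # --- enrichment ------------------------------------------------------
    universe = set(net.nodes)
    known_all = network_build.read_gene_list(cfg.known_genes_path)
    known = known_all & universe
    log["n_known_listed"] = len(known_all)
    log["n_known_in_network"] = len(known)

    annsets = go_enrichment.read_gaf(cfg.gaf_path)
    if cfg.obo_path and cfg.propagate:
        annsets = {ns: go_enrichment.propagate_annotations(a, cfg.obo_path)
                   for ns, a in annsets.items()}
        log["propagated"] = True
    enrichment: dict[str, list] = {}
    ontology_genes: set[str] = set()
    rows = []
    for ns, annset in annsets.items():
        terms = go_enrichment.filter_terms(annset, universe, cfg.min_term, cfg.max_term)
        log[f"n_terms_{ns}"] = len(annset.term2genes)
        log[f"n_terms_filtered_{ns}"] = len(terms)
        res = go_enrichment.enrich(known, universe, annset, terms,
                                   p_threshold=cfg.p_threshold,
                                   bh_correct=cfg.bh_correct)
        enrichment[ns] = res
        ontology_genes |= go_enrichment.genes_of_significant_terms(res, annset, universe)
        for r in res:
            rows.append({
                "term": r.term, "namespace": ns, "N": r.N, "B": r.B,
                "n": r.n, "b": r.b, "p_value": r.p_value,
                "genes": ",".join(r.genes),
            })
    pd.DataFrame(rows, columns=["term", "namespace", "N", "B", "n", "b",
                                "p_value", "genes"]
                 ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    log["n_significant_terms"] = len(rows)
    log["n_ontology_genes"] = len(ontology_genes)

    # --- prediction ------------------------------------------------------
    report = candidate_predict.predict_candidates(pooled, known, ontology_genes)
    coverage = candidate_predict.coverage_summary(known, pooled, ontology_genes)
    allg = sorted(report.set_a | report.set_b | report.set_c)
    pd.DataFrame({
        "gene": allg,
        "in_A": [int(g in report.set_a) for g in allg],
        "in_B": [int(g in report.set_b) for g in allg],
        "in_C": [int(g in report.set_c) for g in allg],
        "is_candidate": [int(g in report.candidates) for g in allg],
    }).to_csv(outdir / "candidate_report.tsv", sep="\t", index=False)
    (outdir / "venn_summary.json").write_text(json.dumps({
        "regions": report.region_counts,
        "candidates": sorted(report.candidates),
        "coverage": coverage,
    }, indent=2) + "\n")
    log["n_candidates"] = len(report.candidates)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")

    return PipelineResult(
        config=cfg, network=net, topology=topo, scores=scores,
        rank_tables=rank_tables, correlation=corr, top_sets=top_sets,
        pooled=pooled, known_in_network=known, enrichment=enrichment,
        ontology_genes=ontology_genes, report=report, coverage=coverage, log=log,
    )
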