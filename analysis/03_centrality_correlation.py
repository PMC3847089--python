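#!/usr/bin/env python
"""Score all ten centrality measures and correlate their rankings.

Computes degree, eccentricity, closeness, centroid value, SP-betweenness,
CF-closeness, CF-betweenness, Katz status, eigenvector and PageRank on
the core network, ranks each, pools the per-measure top-50 gene lists,
and writes the Spearman cross-measure correlation matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from netprio.centrality import undirected_measures
from netprio.network_build import induce_subnetwork, read_edge_list, read_gene_list, remove_orphans
from netprio.rank_stats import correlation_matrix, pool_top_genes, rank_scores, top_k_genes

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "results" / "bundle"
K = 50


def main() -> None:
    ppi = read_edge_list(BUNDLE / "ppi_edges.tsv")
    genes = read_gene_list(BUNDLE / "immunome_genes.txt")
    core = remove_orphans(induce_subnetwork(ppi, genes))

    scores = undirected_measures(core)
    outdir = ROOT / "results" / "undirected"
    outdir.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame({m: pd.Series(t.scores) for m, t in scores.items()})
    wide.rename_axis("gene").to_csv(outdir / "scores_matrix.tsv", sep="\t")

    ranks = {m: rank_scores(t, "average") for m, t in scores.items()}
    corr = correlation_matrix(ranks)
    corr.round(3).to_csv(outdir / "correlation_matrix.tsv", sep="\t")

    tops = {m: top_k_genes(t, K) for m, t in scores.items()}
    pooled = pool_top_genes(tops.values())
    pd.Series(sorted(pooled)).to_csv(outdir / "pooled_top_genes.txt",
                                     index=False, header=False)

    off = corr.values[~np.eye(len(corr), dtype=bool)]
    print(f"{len(scores)} measures scored on {core.n_nodes} genes")
    print(f"  pooled top-{K} list: {len(pooled)} genes")
    print(f"  Spearman off-diagonal range: {off.min():.2f} .. {off.max():.2f}")
    print(f"wrote score matrix, correlation matrix and pooled list to {outdir}")


if __name__ == "__main__":
    main()
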