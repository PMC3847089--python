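#!/usr/bin/env python
"""Build the core network and summarize its topology.

Induces the subnetwork on the gene list, drops orphan nodes (including
the listed genes absent from the interactome), and reports mean degree,
diameter, clustering and the fitted power-law degree exponent gamma.
"""

import json
from pathlib import Path

from netprio.graph_core import topology_summary
from netprio.network_build import induce_subnetwork, read_edge_list, read_gene_list, remove_orphans

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "results" / "bundle"


def main() -> None:
    ppi = read_edge_list(BUNDLE / "ppi_edges.tsv")
    genes = read_gene_list(BUNDLE / "immunome_genes.txt")
    sub = induce_subnetwork(ppi, genes)
    core = remove_orphans(sub)
    t = topology_summary(core)
    summary = {
        "n_listed_genes": len(genes),
        "n_orphans_removed": sub.n_nodes - core.n_nodes,
        "n_nodes": core.n_nodes,
        "n_edges": core.n_edges,
        "average_degree": t.average_degree,
        "diameter": t.diameter,
        "avg_clustering": t.avg_clustering,
        "degree_exponent": t.degree_exponent,
        "n_components": t.n_components,
    }
    out = ROOT / "results" / "topology.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(f"core network: {core.n_nodes} genes, {core.n_edges} interactions "
          f"({summary['n_orphans_removed']} orphans removed)")
    print(f"  mean degree {t.average_degree:.3f}, diameter {t.diameter}, "
          f"clustering {t.avg_clustering:.3f}, gamma {t.degree_exponent:.2f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
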