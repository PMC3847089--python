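#!/usr/bin/env python
"""GO term enrichment of the known disease genes.

Loads the GAF annotations, propagates them up the is_a hierarchy,
keeps terms annotating 3-50 network genes, and tests each for
over-representation of the known disease genes against the network
background (hypergeometric upper tail, p < 0.001 per namespace).
"""

from pathlib import Path

import pandas as pd

from netprio.go_enrichment import (
    enrich,
    filter_terms,
    genes_of_significant_terms,
    propagate_annotations,
    read_gaf,
)
from netprio.network_build import induce_subnetwork, read_edge_list, read_gene_list, remove_orphans

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "results" / "bundle"


def main() -> None:
    ppi = read_edge_list(BUNDLE / "ppi_edges.tsv")
    genes = read_gene_list(BUNDLE / "immunome_genes.txt")
    core = remove_orphans(induce_subnetwork(ppi, genes))
    universe = set(core.nodes)
    known = read_gene_list(BUNDLE / "known_genes.txt") & universe

    annsets = read_gaf(BUNDLE / "annotations.gaf")
    rows, ontology_genes = [], set()
    for ns, annset in annsets.items():
        annset = propagate_annotations(annset, BUNDLE / "ontology.obo")
        terms = filter_terms(annset, universe)
        res = enrich(known, universe, annset, terms)
        ontology_genes |= genes_of_significant_terms(res, annset, universe)
        for r in res:
            rows.append({"term": r.term, "namespace": ns, "N": r.N, "B": r.B,
                         "n": r.n, "b": r.b, "p_value": r.p_value,
                         "genes": ",".join(r.genes)})
        print(f"{ns}: {len(terms)} testable terms, {len(res)} significant")
    outdir = ROOT / "results" / "undirected"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    pd.Series(sorted(ontology_genes)).to_csv(outdir / "ontology_genes.txt",
                                             index=False, header=False)
    print(f"{len(ontology_genes)} genes carry significant disease ontologies")
    print(f"wrote {outdir / 'enrichment.tsv'}")


if __name__ == "__main__":
    main()
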