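from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netprio.graph_core import GeneNetwork
from netprio.pipeline import PipelineConfig, run_pipeline
from netprio.synthetic_data import SyntheticConfig, write_bundle


def net_from_nx(g) -> GeneNetwork:
    return GeneNetwork.from_edges(
        g.edges(), directed=g.is_directed(), extra_nodes=g.nodes()
    )


def path3() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


def cycle4() -> GeneNetwork:
    return GeneNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    )


def star(k: int) -> GeneNetwork:
    return GeneNetwork.from_edges([("HUB", f"L{i}") for i in range(k)])


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Seed-1 synthetic input bundle at the study's default scale."""
    out = tmp_path_factory.mktemp("bundle") / "seed1"
    write_bundle(SyntheticConfig(seed=1), out)
    return out


def _pipeline_config(bundle, mode: str, outdir) -> PipelineConfig:
    edges = "signed_edges.tsv" if mode == "directed" else "ppi_edges.tsv"
    return PipelineConfig(
        ppi_path=str(bundle / edges),
        gene_list_path=str(bundle / "immunome_genes.txt"),
        known_genes_path=str(bundle / "known_genes.txt"),
        gaf_path=str(bundle / "annotations.gaf"),
        obo_path=str(bundle / "ontology.obo"),
        mode=mode,
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def undirected_run(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run_undirected")
    return run_pipeline(_pipeline_config(bundle_dir, "undirected", out))


@pytest.fixture(scope="session")
def directed_run(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run_directed")
    return run_pipeline(_pipeline_config(bundle_dir, "directed", out))


@pytest.fixture
def rng():
    return np.random.default_rng(20130001)
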