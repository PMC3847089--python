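import json

import numpy as np
import pytest
from scipy import stats

from netprio.go_enrichment import filter_terms, read_gaf
from netprio.graph_core import fit_degree_exponent
from netprio.network_build import read_edge_list, read_gene_list
from netprio.synthetic_data import (
    SyntheticConfig,
    generate_annotations,
    generate_network,
    generate_signed_edges,
    plant_disease_genes,
    write_bundle,
)


@pytest.fixture(scope="module")
def cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="module")
def net(cfg):
    return generate_network(cfg)


class TestNetworkGeneration:
    def test_deterministic(self, cfg, net):
        again = generate_network(cfg)
        assert net.edges == again.edges

    def test_edge_count_is_pure_ba_growth(self, net, cfg):
        n, m = cfg.n_nodes, cfg.attachment_m
        assert net.n_edges == m * (n - m)
        assert net.n_nodes == n

    def test_degree_tail_and_exponent(self, net):
        degs = sorted(net.degree().values(), reverse=True)
        counts = np.bincount(degs)
        # heavy decreasing tail: low degrees dominate
        assert counts[3:6].sum() > counts[10:].sum()
        gamma = fit_degree_exponent(list(net.degree().values()))
        assert 1.5 <= gamma <= 3.5


class TestSignedEdges:
    def test_all_plus_fraction(self, net):
        cfg = SyntheticConfig(seed=7, sign_fracs=(1.0, 0.0, 0.0))
        signed = generate_signed_edges(net, cfg)
        assert set(signed.signs.values()) == {"+"}

    def test_deterministic(self, net, cfg):
        s1 = generate_signed_edges(net, cfg)
        s2 = generate_signed_edges(net, cfg)
        assert s1.signs == s2.signs

    def test_fractions_within_binomial_bounds(self, net):
        cfg = SyntheticConfig(seed=7, sign_fracs=(0.5, 0.3, 0.2))
        signed = generate_signed_edges(net, cfg)
        m = len(signed.signs)
        counts = {c: sum(1 for v in signed.signs.values() if v == c)
                  for c in "+-0"}
        for code, frac in zip("+-0", cfg.sign_fracs):
            lo, hi = stats.binom.ppf([0.005, 0.995], m, frac)
            assert lo <= counts[code] <= hi


class TestPlanting:
    def test_sizes_and_disjointness(self, net, cfg):
        known, hidden = plant_disease_genes(net, cfg)
        assert len(known) == cfg.n_known_genes
        assert len(hidden) == cfg.n_planted_candidates
        assert not known & hidden

    def test_deterministic(self, net, cfg):
        assert plant_disease_genes(net, cfg) == plant_disease_genes(net, cfg)

    def test_planted_genes_come_from_top_degree_quartile(self, net, cfg):
        known, hidden = plant_disease_genes(net, cfg)
        deg = net.degree()
        order = sorted(net.nodes, key=lambda v: (-deg[v], v))
        quartile = set(order[: int(np.ceil(net.n_nodes / 4))])
        assert known | hidden <= quartile

    def test_overallocation_errors(self, net):
        cfg = SyntheticConfig(seed=7, n_known_genes=500, n_planted_candidates=8)
        with pytest.raises(ValueError, match="quartile"):
            plant_disease_genes(net, cfg)


class TestAnnotations:
    def test_disease_terms_concentrate_on_planted_genes(self, net, cfg):
        known, hidden = plant_disease_genes(net, cfg)
        terms, _, disease_ids = generate_annotations(net, cfg, known, hidden)
        planted = known | hidden
        fracs = []
        for ns, ids in disease_ids.items():
            for t in ids:
                gs = terms[ns][t]
                fracs.append(len(gs & planted) / len(gs))
        # weighted sampling at the default bias keeps terms nearly pure
        assert min(fracs) >= 0.8
        # every hidden gene annotated to at least one disease term per namespace
        for ns, ids in disease_ids.items():
            covered = set().union(*(terms[ns][t] for t in ids))
            assert hidden <= covered

    def test_boundary_term_sizes_straddle_filter(self, net, cfg):
        known, hidden = plant_disease_genes(net, cfg)
        terms, _, _ = generate_annotations(net, cfg, known, hidden)
        sizes = {len(gs) for t2g in terms.values() for gs in t2g.values()}
        assert 2 in sizes and max(sizes) >= 51


class TestBundle:
    def test_round_trips_and_determinism(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_nodes=120, n_known_genes=20,
                              n_planted_candidates=4)
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        t1 = write_bundle(cfg, d1)
        t2 = write_bundle(cfg, d2)
        for f in ("ppi_edges.tsv", "signed_edges.tsv", "immunome_genes.txt",
                  "known_genes.txt", "annotations.gaf", "ontology.obo",
                  "truth.json"):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()
        assert t1 == t2

        net = read_edge_list(d1 / "ppi_edges.tsv")
        assert net.n_nodes == 120
        signed = read_edge_list(d1 / "signed_edges.tsv", signed=True)
        assert set(signed.signs) == set(net.edges)
        genes = read_gene_list(d1 / "immunome_genes.txt")
        assert len(genes) == 120 + cfg.n_phantom_genes

        annsets = read_gaf(d1 / "annotations.gaf")
        # GAF round-trip reproduces the generated term contents
        from netprio.synthetic_data import generate_annotations, generate_network, plant_disease_genes
        net0 = generate_network(cfg)
        known, hidden = plant_disease_genes(net0, cfg)
        terms, _, _ = generate_annotations(net0, cfg, known, hidden)
        for ns in terms:
            assert annsets[ns].term2genes == terms[ns]

    def test_size2_terms_dropped_downstream(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_nodes=120, n_known_genes=20,
                              n_planted_candidates=4)
        d = tmp_path / "b"
        write_bundle(cfg, d)
        annsets = read_gaf(d / "annotations.gaf")
        universe = read_edge_list(d / "ppi_edges.tsv").nodes
        for ns, a in annsets.items():
            small = {t for t, gs in a.term2genes.items() if len(gs & universe) < 3}
            assert small
            assert not small & filter_terms(a, universe)

    def test_truth_file_consistent(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_nodes=120, n_known_genes=20,
                              n_planted_candidates=4)
        truth = write_bundle(cfg, tmp_path / "b")
        known = read_gene_list(tmp_path / "b" / "known_genes.txt")
        assert set(truth["known_genes"]) == known
        assert not set(truth["hidden_candidates"]) & known
        assert len(truth["hidden_candidates"]) == 4
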