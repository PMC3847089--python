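import numpy as np
import pytest

from netprio.go_enrichment import (
    AnnotationSet,
    enrich,
    filter_terms,
    genes_of_significant_terms,
    hypergeom_tail,
    hypergeom_tail_exact,
    propagate_annotations,
    read_gaf,
)


def gaf_row(gene, term, aspect, qualifier="involved_in"):
    cols = ["DB", gene, gene, qualifier, term, "REF:1", "IEA", "", aspect,
            "", "", "protein", "taxon:9606", "20130101", "DB", "", ""]
    return "\t".join(cols)


def annset(mapping, ns="BP"):
    a = AnnotationSet(ns)
    for term, genes in mapping.items():
        for g in genes:
            a.add(g, term)
    return a


class TestReadGaf:
    def test_not_qualifier_dropped(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text("!gaf-version: 2.2\n" + "\n".join([
            gaf_row("G1", "GO:0000001", "P"),
            gaf_row("G2", "GO:0000001", "P", qualifier="NOT|involved_in"),
            gaf_row("G3", "GO:0000002", "F"),
        ]) + "\n")
        sets = read_gaf(p)
        assert sets["BP"].n_annotations == 1
        assert sets["MF"].n_annotations == 1

    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(gaf_row("G1", "GO:0000001", "P") + "\n"
                     + gaf_row("G1", "GO:0000001", "P") + "\n")
        assert read_gaf(p)["BP"].n_annotations == 1

    def test_malformed_rows_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.gaf"
        p.write_text("bad\trow\n" + gaf_row("G1", "GO:0000001", "C") + "\n")
        with caplog.at_level("WARNING"):
            sets = read_gaf(p)
        assert sets["CC"].n_annotations == 1
        assert any("skipped" in r.message for r in caplog.records)

    def test_zero_usable_rows_errors(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text("!only a comment\n")
        with pytest.raises(ValueError):
            read_gaf(p)

    def test_per_aspect_counts_match_column_tally(self, tmp_path, rng):
        aspects = rng.choice(["P", "F", "C"], size=50).tolist()
        rows = [gaf_row(f"G{i}", f"GO:{i:07d}", a) for i, a in enumerate(aspects, 1)]
        p = tmp_path / "a.gaf"
        p.write_text("\n".join(rows) + "\n")
        sets = read_gaf(p)
        from collections import Counter
        tally = Counter(aspects)
        assert sets["BP"].n_annotations == tally["P"]
        assert sets["MF"].n_annotations == tally["F"]
        assert sets["CC"].n_annotations == tally["C"]
        for s in sets.values():
            s.check_consistency()


def write_obo(tmp_path, stanzas):
    p = tmp_path / "o.obo"
    body = ["format-version: 1.2", ""]
    for tid, parent in stanzas:
        body += ["[Term]", f"id: {tid}", f"name: t", "namespace: biological_process"]
        if parent:
            body.append(f"is_a: {parent} ! p")
        body.append("")
    p.write_text("\n".join(body))
    return p


class TestPropagation:
    def test_gene_gains_ancestor_terms(self, tmp_path):
        obo = write_obo(tmp_path, [("GO:0000001", None), ("GO:0000002", "GO:0000001")])
        a = annset({"GO:0000002": {"g"}})
        out = propagate_annotations(a, obo)
        assert out.terms_of("g") == {"GO:0000001", "GO:0000002"}

    def test_identity_without_parents(self, tmp_path):
        obo = write_obo(tmp_path, [("GO:0000001", None), ("GO:0000002", None)])
        a = annset({"GO:0000001": {"g1"}, "GO:0000002": {"g2"}})
        out = propagate_annotations(a, obo)
        assert out.gene2terms == a.gene2terms

    def test_closure_matches_warshall_oracle(self, tmp_path, rng):
        # random 20-term DAG: term i may have parents among earlier terms
        n = 20
        parents = {}
        edges = []
        for i in range(1, n):
            if rng.random() < 0.7:
                p = int(rng.integers(0, i))
                parents[i] = p
                edges.append((i, p))
        stanzas = [(f"GO:{i + 1:07d}", f"GO:{parents[i] + 1:07d}" if i in parents else None)
                   for i in range(n)]
        obo = write_obo(tmp_path, stanzas)
        a = annset({f"GO:{int(t) + 1:07d}": {f"g{t}"} for t in range(n)})
        out = propagate_annotations(a, obo)
        # Warshall closure over the is_a relation
        reach = np.eye(n, dtype=bool)
        for c, p in edges:
            reach[c, p] = True
        for k in range(n):
            for i in range(n):
                if reach[i, k]:
                    reach[i] |= reach[k]
        for i in range(n):
            expect = {f"GO:{j + 1:07d}" for j in range(n) if reach[i, j]}
            assert out.terms_of(f"g{i}") == expect

    def test_cycle_detected(self, tmp_path):
        obo = write_obo(tmp_path, [("GO:0000001", "GO:0000002"),
                                   ("GO:0000002", "GO:0000001")])
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations(annset({"GO:0000001": {"g"}}), obo)

    def test_propagation_never_shrinks_term_counts(self, tmp_path, rng):
        obo = write_obo(tmp_path, [("GO:0000001", None), ("GO:0000002", "GO:0000001"),
                                   ("GO:0000003", "GO:0000002")])
        a = annset({"GO:0000003": {"g1", "g2"}, "GO:0000002": {"g3"}})
        out = propagate_annotations(a, obo)
        for t, gs in a.term2genes.items():
            assert out.genes_of(t) >= gs


class TestFilterTerms:
    @pytest.mark.parametrize("size,kept", [(2, False), (3, True), (50, True), (51, False)])
    def test_count_boundaries(self, size, kept):
        universe = {f"g{i}" for i in range(60)}
        a = annset({"GO:0000001": {f"g{i}" for i in range(size)}})
        got = filter_terms(a, universe)
        assert ("GO:0000001" in got) is kept

    def test_counts_restricted_to_universe(self):
        a = annset({"GO:0000001": {"g1", "g2", "x1", "x2", "x3"}})
        assert filter_terms(a, {"g1", "g2", "g3"}) == set()

    def test_matches_tally_oracle(self, rng):
        universe = {f"g{i}" for i in range(100)}
        mapping = {
            f"GO:{t:07d}": {f"g{int(i)}" for i in rng.choice(120, int(rng.integers(1, 70)))}
            for t in range(1, 40)
        }
        a = annset(mapping)
        got = filter_terms(a, universe, 3, 50)
        expect = {t for t, gs in mapping.items()
                  if 3 <= len({g for g in gs if g in universe}) <= 50}
        assert got == expect


class TestEnrichment:
    def test_worked_tail_example(self):
        # N=20 background, B=4 annotated, n=5 targets, b=3 hits
        assert hypergeom_tail(20, 4, 5, 3) == pytest.approx(496 / 15504, rel=1e-12)

    def test_zero_hits_never_significant(self):
        assert hypergeom_tail(20, 4, 5, 0) == pytest.approx(1.0)

    def test_certain_event(self):
        assert hypergeom_tail(10, 10, 10, 10) == pytest.approx(1.0)

    def test_monotone_in_b(self):
        ps = [hypergeom_tail(30, 10, 12, b) for b in range(0, 11)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_enrich_returns_sorted_significant_terms(self):
        universe = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(5)}
        a = annset({
            "GO:0000001": {"g0", "g1", "g2", "g3"},        # enriched in target
            "GO:0000002": {"g15", "g16", "g17", "g18"},    # disjoint from target
        })
        res = enrich(target, universe, a, p_threshold=0.05)
        assert [r.term for r in res] == ["GO:0000001"]
        r = res[0]
        assert (r.N, r.B, r.n, r.b) == (20, 4, 5, 4)
        assert r.genes == ("g0", "g1", "g2", "g3")

    def test_target_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(12)}
        a = annset({"GO:0000001": {"g0", "g1", "g2"}})
        res = enrich(universe, universe, a, p_threshold=1.1)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_target_outside_universe_errors(self):
        with pytest.raises(ValueError, match="not in the background"):
            enrich({"x"}, {"a", "b"}, annset({}))

    def test_exact_tail_on_small_grid(self):
        # spot grid here; the exhaustive N<=30 sweep runs in the acceptance suite
        for N in (5, 11, 17):
            for B in range(N + 1):
                for n in range(N + 1):
                    for b in range(0, min(B, n) + 1):
                        exact = float(hypergeom_tail_exact(N, B, n, b))
                        assert hypergeom_tail(N, B, n, b) == pytest.approx(
                            exact, abs=1e-12)


class TestSignificantGenes:
    def test_union_of_term_genes(self):
        a = annset({"GO:0000001": {"a", "b"}, "GO:0000002": {"b", "c"}})
        res = enrich({"a", "b", "c"}, {"a", "b", "c", "d"}, a, p_threshold=1.1)
        got = genes_of_significant_terms(res, a, {"a", "b", "c", "d"})
        assert got == {"a", "b", "c"}

    def test_no_significant_terms_empty(self):
        a = annset({"GO:0000001": {"a"}})
        assert genes_of_significant_terms([], a, {"a"}) == set()
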