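"""Gene mapping by coverage fraction and Fisher term enrichment."""

import pytest
from conftest import hypergeom_tail_exact, make_call

from cnvconsensus.annotation import TermCatalog, fisher_enrichment, map_genes
from cnvconsensus.consensus import build_consensus
from cnvconsensus.core import Direction, GeneModel, GenomicInterval, normalize_callset


def _consensus(calls_by_caller, sample="s"):
    callsets = [
        normalize_callset(calls, caller=caller, sample=sample)
        for caller, calls in calls_by_caller.items()
    ]
    return build_consensus(callsets)


def _gene(gene_id, chrom, start, end):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end))


class TestMapGenes:
    def test_exact_boundary_is_inclusive(self):
        """A gene with exactly 70% of its sequence inside the region passes
        the default 0.7 threshold."""
        res = _consensus({"A": [make_call("chr1", 0, 700, 3, "A")]})
        hits = map_genes(res, [_gene("G1", "chr1", 0, 1000)], coverage=0.7)
        assert [a.gene_id for a in hits] == ["G1"]
        assert hits[0].coverage_fraction == pytest.approx(0.7)
        assert hits[0].multiplicity_class == 1
        assert hits[0].supporting_callers == frozenset({"A"})

    def test_one_base_below_boundary_is_excluded(self):
        res = _consensus({"A": [make_call("chr1", 0, 699, 3, "A")]})
        assert map_genes(res, [_gene("G1", "chr1", 0, 1000)], coverage=0.7) == []

    def test_union_coverage_across_same_class_regions(self):
        """Coverage accumulates over the union of one class's regions:
        400 + 400 covered bp of a 1000 bp gene = 0.8 >= 0.7."""
        res = _consensus(
            {"A": [make_call("chr1", 0, 400, 3, "A"), make_call("chr1", 500, 900, 4, "A")]}
        )
        hits = map_genes(res, [_gene("G1", "chr1", 0, 1000)], coverage=0.7)
        assert [a.gene_id for a in hits] == ["G1"]
        assert hits[0].coverage_fraction == pytest.approx(0.8)

    def test_tiny_threshold_keeps_any_overlap_full_requires_containment(self):
        res = _consensus({"A": [make_call("chr1", 500, 1500, 3, "A")]})
        genes = [
            _gene("Gin", "chr1", 600, 700),     # fully contained
            _gene("Gedge", "chr1", 1400, 1600), # half inside
            _gene("Gout", "chr1", 2000, 2100),  # disjoint
        ]
        tiny = map_genes(res, genes, coverage=1e-9)
        assert {a.gene_id for a in tiny} == {"Gin", "Gedge"}
        full = map_genes(res, genes, coverage=1.0)
        assert {a.gene_id for a in full} == {"Gin"}

    def test_classes_and_directions_are_separate(self):
        res = _consensus(
            {
                "A": [make_call("chr1", 0, 1000, 3, "A")],
                "B": [make_call("chr1", 0, 500, 5, "B"), make_call("chr2", 0, 800, 1, "B")],
            }
        )
        genes = [_gene("G1", "chr1", 0, 500), _gene("G2", "chr2", 0, 800)]
        hits = map_genes(res, genes, coverage=0.7)
        by_gene = {(a.gene_id): a for a in hits}
        assert by_gene["G1"].multiplicity_class == 2
        assert by_gene["G1"].direction is Direction.GAIN
        assert by_gene["G1"].supporting_callers == frozenset({"A", "B"})
        assert by_gene["G2"].multiplicity_class == 1
        assert by_gene["G2"].direction is Direction.LOSS

    def test_invalid_threshold_rejected(self):
        res = _consensus({"A": [make_call("chr1", 0, 10, 3, "A")]})
        for bad in (0, -0.5, 1.5):
            with pytest.raises(ValueError):
                map_genes(res, [], coverage=bad)


class TestFisherEnrichment:
    def _catalog(self, **terms):
        return TermCatalog(
            catalog_name="cat",
            terms={t: (f"term {t}", frozenset(genes)) for t, genes in terms.items()},
        )

    def test_no_overlap_gives_p_exactly_one(self):
        cat = self._catalog(T1=["G1", "G2"])
        universe = {f"G{i}" for i in range(1, 21)}
        recs = fisher_enrichment({"G10", "G11"}, cat, universe)
        assert recs[0].a == 0
        assert recs[0].p_value == 1.0

    def test_cnv_genes_equal_universe_degenerate(self):
        universe = {f"G{i}" for i in range(1, 21)}
        cat = self._catalog(T1=["G1", "G2"], T2=["G3", "G4", "G5"])
        recs = fisher_enrichment(universe, cat, universe)
        assert all(r.p_value == 1.0 for r in recs)

    def test_counts_partition_the_universe(self):
        universe = {f"G{i}" for i in range(1, 101)}
        cat = self._catalog(T1=[f"G{i}" for i in range(1, 6)])
        recs = fisher_enrichment({f"G{i}" for i in range(1, 11)}, cat, universe)
        r = recs[0]
        assert (r.a, r.b, r.c, r.d) == (5, 5, 0, 90)
        assert r.a + r.b + r.c + r.d == 100

    def test_specific_table_matches_exact_tail(self):
        """a=3, b=7, c=2, d=88 against the exact rational tail sum."""
        universe = [f"G{i}" for i in range(100)]
        cnv = set(universe[:10])                       # a+b = 10
        term = set(universe[:3]) | set(universe[10:12])  # a=3, c=2
        cat = self._catalog(T1=term)
        rec = fisher_enrichment(cnv, cat, universe)[0]
        assert (rec.a, rec.b, rec.c, rec.d) == (3, 7, 2, 88)
        expected = float(hypergeom_tail_exact(3, 7, 2, 88))
        assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_random_tables_match_exact_tail(self, rng):
        """One-sided p equals the exact hypergeometric tail on random
        small tables (N <= 200)."""
        for _ in range(300):
            n_universe = int(rng.integers(4, 201))
            universe = [f"G{i}" for i in range(n_universe)]
            n_cnv = int(rng.integers(1, n_universe + 1))
            n_term = int(rng.integers(1, n_universe + 1))
            cnv = set(rng.choice(universe, size=n_cnv, replace=False))
            term = set(rng.choice(universe, size=n_term, replace=False))
            rec = fisher_enrichment(cnv, self._catalog(T1=term), universe)[0]
            expected = float(hypergeom_tail_exact(rec.a, rec.b, rec.c, rec.d))
            assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_properties(self, rng):
        universe = [f"G{i}" for i in range(150)]
        terms = {}
        for t in range(25):
            size = int(rng.integers(2, 30))
            terms[f"T{t:02d}"] = set(rng.choice(universe, size=size, replace=False))
        cnv = set(rng.choice(universe, size=30, replace=False))
        recs = fisher_enrichment(cnv, self._catalog(**terms), universe)
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in recs)
        ordered = sorted(recs, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in ordered]
        assert all(x <= y + 1e-15 for x, y in zip(adj, adj[1:]))
        # records come back sorted by (p, term)
        assert [(r.p_value, r.term_id) for r in recs] == sorted(
            (r.p_value, r.term_id) for r in recs
        )

    def test_growing_background_never_raises_one_sided_p(self, rng):
        """Adding genes outside every term and outside the CNV set only
        grows d, and the enrichment p-value never increases."""
        universe = [f"G{i}" for i in range(40)]
        cnv = set(universe[:8])
        term = set(universe[:4]) | set(universe[20:24])
        cat = self._catalog(T1=term)
        p_prev = fisher_enrichment(cnv, cat, universe)[0].p_value
        for extra in (10, 50, 200):
            bigger = universe + [f"X{i}" for i in range(extra)]
            p_new = fisher_enrichment(cnv, cat, bigger)[0].p_value
            assert p_new <= p_prev + 1e-12
            p_prev = p_new

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"G1"}, self._catalog(T1=["G1"]), set())

    def test_term_outside_universe_skipped_with_warning(self, caplog):
        cat = self._catalog(T1=["Z1", "Z2"], T2=["G1"])
        with caplog.at_level("WARNING"):
            recs = fisher_enrichment({"G1"}, cat, {"G1", "G2"})
        assert [r.term_id for r in recs] == ["T2"]
        assert any("T1" in rec.message for rec in caplog.records)

    def test_empty_term_rejected_at_catalog_level(self):
        with pytest.raises(ValueError):
            TermCatalog("cat", {"T1": ("d", frozenset())})
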