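"""Gene-to-CNV-class mapping and Fisher's-exact-test term enrichment.

A gene is assigned to a sharing class (per direction) when the fraction
of its sequence covered by that class's merged regions reaches the
coverage threshold (default 0.7, inclusive).  Enrichment of the mapped
genes against a term catalog uses the one-sided (greater) Fisher exact
test on the standard 2x2 table over a background gene universe, with
Benjamini-Hochberg adjustment within each catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusResult, class_regions
from .core import Direction, GeneModel, intersect_intervals, total_bp

__all__ = [
    "GeneAssignment",
    "TermCatalog",
    "EnrichmentRecord",
    "map_genes",
    "fisher_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAssignment:
    """A gene linked to one (multiplicity class, direction) CNV region set."""

    gene_id: str
    multiplicity_class: int
    direction: Direction
    coverage_fraction: float
    supporting_callers: frozenset[str]


@dataclass(frozen=True)
class TermCatalog:
    """A named collection of gene sets (GO / KEGG / OMIM / COG / domain ...)."""

    catalog_name: str
    terms: Mapping[str, tuple[str, frozenset[str]]]  # term_id -> (description, genes)

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's 2x2 Fisher result.

    Counts: a = CNV genes in the term, b = CNV genes outside it,
    c = background-only genes in the term, d = background-only genes
    outside it; all restricted to the universe.
    """

    term_id: str
    catalog_name: str
    description: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float  # inf when b*c == 0 and a*d > 0; nan when 0/0
    p_value: float
    p_adjusted: float


def map_genes(
    result: ConsensusResult,
    genes: Sequence[GeneModel],
    coverage: float = 0.7,
) -> list[GeneAssignment]:
    """Assign genes to multiplicity classes by coverage fraction.

    For each class k and direction, a gene's coverage fraction is the bp of
    the gene overlapped by the union of that class's merged regions divided
    by the gene length; the gene is retained when the fraction is >= the
    threshold (inclusive, computed in exact rational arithmetic so a gene
    covered at exactly 70% passes a 0.7 threshold).  ``supporting_callers``
    is the union of supporters over the consensus segments of that class
    overlapping the gene.
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage threshold must be in (0, 1], got {coverage}")
    threshold = Fraction(str(coverage))
    assignments: list[GeneAssignment] = []
    for k in range(1, result.max_multiplicity() + 1):
        regions = class_regions(result, k)
        for direction in (Direction.GAIN, Direction.LOSS):
            if not regions[direction]:
                continue
            segs = [
                s
                for s in result.segments
                if s.direction == direction and s.multiplicity == k
            ]
            for gene in genes:
                covered = total_bp(
                    intersect_intervals([gene.interval], regions[direction])
                )
                frac = Fraction(covered, gene.interval.length())
                if frac >= threshold:
                    supporters: set[str] = set()
                    for s in segs:
                        if (
                            s.interval.chrom == gene.interval.chrom
                            and s.interval.start < gene.interval.end
                            and gene.interval.start < s.interval.end
                        ):
                            supporters |= s.supporting_callers
                    assignments.append(
                        GeneAssignment(
                            gene_id=gene.gene_id,
                            multiplicity_class=k,
                            direction=direction,
                            coverage_fraction=float(frac),
                            supporting_callers=frozenset(supporters),
                        )
                    )
    assignments.sort(
        key=lambda a: (a.multiplicity_class, a.direction.value, a.gene_id)
    )
    return assignments


def fisher_enrichment(
    cnv_genes: Iterable[str],
    catalog: TermCatalog,
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """One-sided Fisher enrichment of ``cnv_genes`` against every catalog term.

    The 2x2 table is formed over the universe; the p-value is the upper
    hypergeometric tail P(X >= a) with X ~ Hypergeom(N=a+b+c+d, K=a+c,
    n=a+b).  Terms with no genes in the universe are skipped with a
    warning.  Records are BH-adjusted within the catalog and sorted by
    (p_value, term_id).
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    hits = frozenset(cnv_genes) & universe_set
    n_universe = len(universe_set)
    n_hits = len(hits)

    records: list[EnrichmentRecord] = []
    for term_id in sorted(catalog.terms):
        description, term_genes = catalog.terms[term_id]
        term_in_universe = term_genes & universe_set
        if not term_in_universe:
            logger.warning(
                "term %s (%s) has no genes in the universe; skipped",
                term_id,
                catalog.catalog_name,
            )
            continue
        a = len(hits & term_in_universe)
        b = n_hits - a
        c = len(term_in_universe) - a
        d = n_universe - a - b - c
        # upper tail P(X >= a); sf(a-1) is exact for the integer support
        p = float(hypergeom.sf(a - 1, n_universe, a + c, a + b))
        p = min(1.0, max(0.0, p))
        if b * c > 0:
            odds = (a * d) / (b * c)
        elif a * d > 0:
            odds = float("inf")
        else:
            odds = float("nan")
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                catalog_name=catalog.catalog_name,
                description=description,
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=odds,
                p_value=p,
                p_adjusted=p,  # placeholder, replaced below
            )
        )

    if records:
        _, adjusted, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        records = [
            EnrichmentRecord(
                term_id=r.term_id,
                catalog_name=r.catalog_name,
                description=r.description,
                a=r.a,
                b=r.b,
                c=r.c,
                d=r.d,
                odds_ratio=r.odds_ratio,
                p_value=r.p_value,
                p_adjusted=float(adj),
            )
            for r, adj in zip(records, adjusted)
        ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records
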