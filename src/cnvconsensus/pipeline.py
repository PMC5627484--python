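"""One-call orchestration: config in, tables + HTML report out.

``run_pipeline`` executes read -> consensus -> min-caller filter ->
gene mapping -> enrichment (per catalog) -> evaluation (when a truth
profile is supplied) -> table writing -> report rendering.  Outputs are
deterministic: running the same configuration twice produces
byte-identical TSVs and HTML.  The ``threads`` setting is accepted for
interface compatibility and validated, but stages run serially — the
output contract (identical to a serial run) holds for every thread
count by construction.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from .annotation import fisher_enrichment, map_genes
from .consensus import build_consensus, filter_min_callers
from .core import GenomicInterval, chrom_sort_key
from .evaluation import TruthProfile, evaluate_thresholds
from .io import (
    DIALECTS,
    PipelineConfig,
    read_config,
    read_gene_bed,
    read_genome_tsv,
    read_gmt,
    read_seg,
    write_tables,
)
from .report import ReportBundle, render_html

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig | str | Path) -> ReportBundle:
    """Run the whole pipeline for one sample and write all outputs.

    Returns the :class:`ReportBundle` whose contents back both the TSV
    tables and ``report.html`` in ``config.output_dir``.
    """
    if not isinstance(config, PipelineConfig):
        config = read_config(config)

    logger.info("reading %d caller seg file(s)", len(config.callers))
    callsets = [
        read_seg(path, DIALECTS[dialect], caller=name, sample=config.sample)
        for name, path, dialect in config.callers
    ]

    logger.info("building consensus segmentation")
    consensus = build_consensus(callsets)
    filtered = filter_min_callers(consensus, config.min_callers)

    gene_assignments = []
    genes = []
    if config.gene_bed_path:
        genes = read_gene_bed(config.gene_bed_path)
        logger.info("mapping %d genes at coverage >= %g", len(genes), config.gene_coverage)
        gene_assignments = map_genes(filtered, genes, coverage=config.gene_coverage)

    enrichment = []
    if config.term_catalog_paths:
        if not genes:
            raise ValueError("term catalogs require a gene_bed for the universe")
        cnv_genes = {a.gene_id for a in gene_assignments}
        universe = {g.gene_id for g in genes}
        for cat_path in config.term_catalog_paths:
            catalog = read_gmt(cat_path)
            logger.info("enrichment against catalog %s (%d terms)",
                        catalog.catalog_name, len(catalog.terms))
            enrichment.extend(fisher_enrichment(cnv_genes, catalog, universe))

    metrics = None
    if config.truth_path:
        if not config.genome_path:
            raise ValueError("evaluation against a truth profile requires a genome file")
        chroms = read_genome_tsv(config.genome_path)
        assay = [
            GenomicInterval(c, 0, l)
            for c, l in sorted(chroms.items(), key=lambda kv: chrom_sort_key(kv[0]))
        ]
        truth_cs = read_seg(
            config.truth_path, DIALECTS["seg"], caller="truth", sample=config.sample
        )
        truth = TruthProfile(sample=config.sample, events=truth_cs.calls)
        logger.info("evaluating against truth profile (%d events)", len(truth.events))
        metrics = evaluate_thresholds(callsets, truth, assay, consensus=consensus)

    logger.info("plot rendering skipped; tables are the source of truth")
    tables = write_tables(
        config.output_dir,
        callsets=callsets,
        consensus=filtered,
        gene_assignments=gene_assignments,
        enrichment=enrichment,
        metrics=metrics,
    )

    # threads and output_dir are execution details, not analysis parameters:
    # leaving them out keeps the report byte-identical across thread counts
    # and relocations of the output directory
    echo = {
        k: str(v)
        for k, v in dataclasses.asdict(config).items()
        if v not in (None, (), "") and k not in ("threads", "output_dir")
    }
    bundle = ReportBundle(
        sample=config.sample,
        callsets=callsets,
        consensus=filtered,
        gene_assignments=gene_assignments,
        enrichment=enrichment,
        metrics=metrics,
        config_echo=echo,
        seed=config.seed,
        tables=tables,
    )
    report_path = Path(config.output_dir) / "report.html"
    report_path.write_text(render_html(bundle))
    logger.info("wrote %s and %d table(s)", report_path, len(tables))
    return bundle
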