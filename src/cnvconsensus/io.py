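"""Readers and writers for every on-disk format the pipeline touches.

Segment files from different CNV callers arrive in slightly different
tab-separated layouts and coordinate conventions; a :class:`SegDialect`
describes one layout (column roles, 0-based half-open vs 1-based
inclusive coordinates, header, comment prefix) and every reader converts
to the package-internal 0-based half-open convention on the way in.

Built-in dialect presets exist for the four callers the consensus
approach was designed around ("freec", "adtex", "excavator", "exomecnv");
their column layouts are this package's conventions for plain
chrom/start/end/copy-number tables, not transcriptions of those tools'
native outputs — reconfigure or add dialects as needed.  "seg" is the
internal default (0-based half-open, with header) and "bed5" a BED-style
layout with the copy number in column 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import EnrichmentRecord, GeneAssignment, TermCatalog
from .consensus import ConsensusResult
from .core import (
    CallSet,
    CnvCall,
    DIPLOID_CN,
    GeneModel,
    GenomicInterval,
    chrom_sort_key,
    normalize_callset,
)

__all__ = [
    "SegDialect",
    "DIALECTS",
    "PipelineConfig",
    "read_config",
    "read_seg",
    "write_seg",
    "read_gene_bed",
    "write_gene_bed",
    "read_gmt",
    "write_gmt",
    "read_genome_tsv",
    "write_genome_tsv",
    "write_config",
    "write_metrics",
    "write_tables",
]

logger = logging.getLogger(__name__)

ZERO_HALF_OPEN = "zero_half_open"
ONE_INCLUSIVE = "one_inclusive"


@dataclass(frozen=True)
class SegDialect:
    """Layout of one caller's segment file."""

    name: str
    column_map: dict[str, int] = field(
        default_factory=lambda: {"chrom": 0, "start": 1, "end": 2, "copy_number": 3}
    )
    coordinate_base: str = ZERO_HALF_OPEN
    has_header: bool = True
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "copy_number"}
        if set(self.column_map) < required:
            raise ValueError(f"column_map must cover {sorted(required)}")
        idx = list(self.column_map.values())
        if len(set(idx)) != len(idx):
            raise ValueError("column indices must be distinct")
        if self.coordinate_base not in (ZERO_HALF_OPEN, ONE_INCLUSIVE):
            raise ValueError(f"unknown coordinate base {self.coordinate_base!r}")


DIALECTS: dict[str, SegDialect] = {
    "seg": SegDialect(name="seg"),
    "bed5": SegDialect(
        name="bed5",
        column_map={"chrom": 0, "start": 1, "end": 2, "copy_number": 4},
        has_header=False,
    ),
    "freec": SegDialect(name="freec", coordinate_base=ONE_INCLUSIVE, has_header=False),
    "adtex": SegDialect(name="adtex", coordinate_base=ONE_INCLUSIVE),
    "excavator": SegDialect(name="excavator", coordinate_base=ONE_INCLUSIVE),
    "exomecnv": SegDialect(name="exomecnv", coordinate_base=ONE_INCLUSIVE),
}


def read_seg(
    path: str | Path, dialect: SegDialect, caller: str, sample: str
) -> CallSet:
    """Parse one caller's segment file into a normalized :class:`CallSet`.

    Coordinates are converted to 0-based half-open; direction is derived
    from the copy number; rows at the diploid baseline (CN=2) are skipped
    with a warning.  Unparseable rows and empty intervals raise with the
    offending line number.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect.comment_prefix and line.startswith(dialect.comment_prefix):
                continue
            if dialect.has_header and first_data:
                first_data = False
                continue
            first_data = False
            fields = line.split("\t")
            try:
                chrom = fields[dialect.column_map["chrom"]]
                start = int(fields[dialect.column_map["start"]])
                end = int(fields[dialect.column_map["end"]])
                cn = int(float(fields[dialect.column_map["copy_number"]]))
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse row under dialect "
                    f"{dialect.name!r}: {line!r}"
                ) from exc
            if dialect.coordinate_base == ONE_INCLUSIVE:
                start -= 1  # 1-based inclusive start -> 0-based; end already matches
            if cn == DIPLOID_CN:
                logger.warning(
                    "%s:%d: copy number 2 is the diploid baseline; row skipped",
                    path,
                    lineno,
                )
                continue
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: empty or negative interval "
                    f"[{start}, {end}) after coordinate conversion"
                )
            calls.append(
                CnvCall.from_copy_number(GenomicInterval(chrom, start, end), cn, caller, sample)
            )
    return normalize_callset(calls, caller=caller, sample=sample)


def write_seg(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the internal 'seg' dialect (0-based half-open)."""
    rows = sorted(calls, key=lambda c: (chrom_sort_key(c.interval.chrom), c.interval.start))
    with Path(path).open("w") as fh:
        fh.write("chrom\tstart\tend\tcopy_number\tdirection\n")
        for c in rows:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.copy_number}\t{c.direction.value}\n"
            )


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED4+ (chrom, start, end, gene id).

    Coordinates are preserved as 0-based half-open; duplicate gene ids and
    missing name columns are errors.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: gene BED needs >= 4 columns "
                    "(chrom, start, end, gene id); the name column is missing"
                )
            chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end)))
    genes.sort(key=lambda g: (chrom_sort_key(g.interval.chrom), g.interval.start))
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (chrom_sort_key(g.interval.chrom), g.interval.start))
    with Path(path).open("w") as fh:
        for g in rows:
            fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\n")


def read_gmt(path: str | Path, catalog_name: str | None = None) -> TermCatalog:
    """Read a GMT gene-set file (term, description, gene ids...).

    Duplicate term names are merged by gene-set union with a warning.
    """
    path = Path(path)
    name = catalog_name or path.stem
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        n_lines = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    "(term, description, >= 1 gene)"
                )
            term_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if term_id in terms:
                logger.warning(
                    "%s:%d: duplicate term %r merged by gene-set union", path, lineno, term_id
                )
                old_desc, old_genes = terms[term_id]
                terms[term_id] = (old_desc, old_genes | genes)
            else:
                terms[term_id] = (desc, genes)
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return TermCatalog(catalog_name=name, terms=terms)


def write_gmt(catalog: TermCatalog, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term_id in sorted(catalog.terms):
            desc, genes = catalog.terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def read_genome_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-length table (chrom <TAB> length)."""
    chroms: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            chroms[fields[0]] = int(fields[1])
    if not chroms:
        raise ValueError(f"{path}: no chromosomes")
    return chroms


def write_genome_tsv(chromosomes: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(chromosomes, key=chrom_sort_key):
            fh.write(f"{chrom}\t{chromosomes[chrom]}\n")


# ---------------------------------------------------------------------------
# Pipeline config: flat case-insensitive key=value text.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``callers`` holds (caller name, seg path, dialect name) triples; the
    config file lists one ``caller = name,path,dialect`` line per caller
    (dialect defaults to 'seg' when omitted).
    """

    callers: tuple[tuple[str, str, str], ...]
    output_dir: str
    sample: str = "sample"
    gene_bed_path: str | None = None
    term_catalog_paths: tuple[str, ...] = ()
    truth_path: str | None = None
    genome_path: str | None = None
    gene_coverage: float = 0.7
    min_callers: int = 1
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.callers:
            raise ValueError("config needs >= 1 caller")
        names = [c[0] for c in self.callers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate caller names in config: {names}")
        if not (0 < self.gene_coverage <= 1):
            raise ValueError("gene_coverage must be in (0, 1]")
        if not (1 <= self.min_callers <= len(self.callers)):
            raise ValueError(
                f"min_callers must be in [1, {len(self.callers)}], got {self.min_callers}"
            )
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        for _, _, dialect in self.callers:
            if dialect not in DIALECTS:
                raise ValueError(
                    f"unknown seg dialect {dialect!r}; known: {sorted(DIALECTS)}"
                )


_REQUIRED_KEYS = {"caller", "output_dir"}
_KNOWN_KEYS = _REQUIRED_KEYS | {
    "sample",
    "gene_bed",
    "term_catalog",
    "truth",
    "genome",
    "gene_coverage",
    "min_callers",
    "threads",
    "seed",
}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse the flat key=value config file (keys case-insensitive).

    Repeatable keys: ``caller`` and ``term_catalog``.  Unknown keys warn;
    missing required keys error.
    """
    path = Path(path)
    callers: list[tuple[str, str, str]] = []
    catalogs: list[str] = []
    scalars: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip().lower(), value.strip()
            if key not in _KNOWN_KEYS:
                logger.warning("%s:%d: unknown config key %r ignored", path, lineno, key)
                continue
            if key == "caller":
                parts = [p.strip() for p in value.split(",")]
                if len(parts) == 2:
                    parts.append("seg")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: caller value must be 'name,path[,dialect]'"
                    )
                callers.append((parts[0], parts[1], parts[2]))
            elif key == "term_catalog":
                catalogs.append(value)
            else:
                scalars[key] = value
    missing = [k for k in _REQUIRED_KEYS if (k == "caller" and not callers) or (k != "caller" and k not in scalars)]
    if missing:
        raise ValueError(f"{path}: missing required config keys: {missing}")
    return PipelineConfig(
        callers=tuple(callers),
        output_dir=scalars["output_dir"],
        sample=scalars.get("sample", "sample"),
        gene_bed_path=scalars.get("gene_bed"),
        term_catalog_paths=tuple(catalogs),
        truth_path=scalars.get("truth"),
        genome_path=scalars.get("genome"),
        gene_coverage=float(scalars.get("gene_coverage", "0.7")),
        min_callers=int(scalars.get("min_callers", "1")),
        threads=int(scalars.get("threads", "1")),
        seed=int(scalars.get("seed", "0")),
    )


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, seg_path, dialect in config.callers:
            fh.write(f"caller = {name},{seg_path},{dialect}\n")
        fh.write(f"output_dir = {config.output_dir}\n")
        fh.write(f"sample = {config.sample}\n")
        if config.gene_bed_path:
            fh.write(f"gene_bed = {config.gene_bed_path}\n")
        for cat in config.term_catalog_paths:
            fh.write(f"term_catalog = {cat}\n")
        if config.truth_path:
            fh.write(f"truth = {config.truth_path}\n")
        if config.genome_path:
            fh.write(f"genome = {config.genome_path}\n")
        fh.write(f"gene_coverage = {config.gene_coverage}\n")
        fh.write(f"min_callers = {config.min_callers}\n")
        fh.write(f"threads = {config.threads}\n")
        fh.write(f"seed = {config.seed}\n")


# ---------------------------------------------------------------------------
# Result tables.  All writers are bit-stable for a fixed input: fixed row
# order (natural chromosome sort), fixed float formatting.
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_tables(
    output_dir: str | Path,
    callsets: Sequence[CallSet] = (),
    consensus: ConsensusResult | None = None,
    gene_assignments: Sequence[GeneAssignment] = (),
    enrichment: Sequence[EnrichmentRecord] = (),
    metrics=None,
) -> dict[str, Path]:
    """Write the pipeline's TSV outputs; returns {table name: path}.

    Emits per_caller_calls.tsv, consensus.tsv, genes.tsv, enrichment.tsv
    and venn_counts.tsv (plus metrics.tsv when an evaluation table is
    given).  Re-running on identical inputs produces byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = []
    for cs in sorted(callsets, key=lambda c: c.caller):
        for c in cs.calls:
            rows.append(
                [c.interval.chrom, c.interval.start, c.interval.end,
                 c.copy_number, c.direction.value, c.caller]
            )
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1], r[5]))
    p = out / "per_caller_calls.tsv"
    _write_tsv(p, ["chrom", "start", "end", "copy_number", "direction", "caller"], rows)
    written["per_caller_calls"] = p

    rows = []
    if consensus is not None:
        for s in consensus.segments:
            supporters = sorted(s.supporting_callers)
            rows.append(
                [
                    s.interval.chrom,
                    s.interval.start,
                    s.interval.end,
                    s.direction.value,
                    s.multiplicity,
                    s.multiplicity_class,
                    ",".join(supporters),
                    ",".join(f"{c}={s.per_caller_cn[c]}" for c in supporters),
                ]
            )
        rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1], r[3]))
    p = out / "consensus.tsv"
    _write_tsv(
        p,
        ["chrom", "start", "end", "direction", "multiplicity", "class", "callers", "per_caller_cn"],
        rows,
    )
    written["consensus"] = p

    rows = [
        [a.gene_id, a.multiplicity_class, a.direction.value,
         a.coverage_fraction, ",".join(sorted(a.supporting_callers))]
        for a in gene_assignments
    ]
    p = out / "genes.tsv"
    _write_tsv(p, ["gene", "multiplicity_class", "direction", "coverage_fraction", "callers"], rows)
    written["genes"] = p

    rows = [
        [r.term_id, r.catalog_name, r.description, r.a, r.b, r.c, r.d,
         r.odds_ratio, r.p_value, r.p_adjusted]
        for r in enrichment
    ]
    p = out / "enrichment.tsv"
    _write_tsv(
        p,
        ["term", "catalog", "description", "a", "b", "c", "d", "odds_ratio", "p_value", "p_adjusted"],
        rows,
    )
    written["enrichment"] = p

    rows = []
    if consensus is not None:
        for (subset, direction), (count, bp) in consensus.venn_counts.items():
            rows.append([",".join(sorted(subset)), direction.value, count, bp])
        rows.sort(key=lambda r: (len(r[0].split(",")), r[0], r[1]))
    p = out / "venn_counts.tsv"
    _write_tsv(p, ["callers", "direction", "region_count", "total_bp"], rows)
    written["venn_counts"] = p

    if metrics is not None:
        p = out / "metrics.tsv"
        write_metrics(metrics, p)
        written["metrics"] = p

    return written


def write_metrics(metrics, path: str | Path) -> None:
    """Write an evaluation table (from evaluate_thresholds) as TSV."""
    rows = []
    for _, r in metrics.iterrows():
        rows.append(
            [r["sample"], r["call_set"], int(r["tp_bp"]), int(r["fp_bp"]),
             int(r["fn_bp"]), int(r["tn_bp"]),
             None if _isna(r["tpr"]) else float(r["tpr"]),
             None if _isna(r["fdr"]) else float(r["fdr"]),
             None if _isna(r["precision"]) else float(r["precision"])]
        )
    _write_tsv(
        Path(path),
        ["sample", "call_set", "tp_bp", "fp_bp", "fn_bp", "tn_bp", "tpr", "fdr", "precision"],
        rows,
    )


def _isna(x) -> bool:
    import pandas as pd

    return x is None or pd.isna(x)
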