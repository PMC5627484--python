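"""Self-contained HTML report over the pipeline's result tables.

Every number shown in the HTML is rendered from the same in-memory
objects the TSV writers serialize, so report and tables always agree.
The page embeds no external resources and carries no timestamps, so a
fixed input regenerates it byte-identically.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import EnrichmentRecord, GeneAssignment
from .consensus import ConsensusResult
from .core import CallSet, Direction, chrom_sort_key

__all__ = ["ReportBundle", "summarize_caller", "render_html"]


def summarize_caller(callset: CallSet) -> dict:
    """Per-caller gain/loss event counts and bp, per chromosome and total."""
    per_chrom: dict[str, dict[str, int]] = {}
    totals = {"gain_count": 0, "loss_count": 0, "gain_bp": 0, "loss_bp": 0}
    for c in callset.calls:
        d = per_chrom.setdefault(
            c.interval.chrom, {"gain_count": 0, "loss_count": 0, "gain_bp": 0, "loss_bp": 0}
        )
        key = "gain" if c.direction == Direction.GAIN else "loss"
        d[f"{key}_count"] += 1
        d[f"{key}_bp"] += c.interval.length()
        totals[f"{key}_count"] += 1
        totals[f"{key}_bp"] += c.interval.length()
    return {
        "caller": callset.caller,
        "total": totals,
        "per_chromosome": dict(sorted(per_chrom.items(), key=lambda kv: chrom_sort_key(kv[0]))),
    }


@dataclass
class ReportBundle:
    """Everything the HTML report renders, in one place."""

    sample: str
    callsets: Sequence[CallSet] = ()
    consensus: ConsensusResult | None = None
    gene_assignments: Sequence[GeneAssignment] = ()
    enrichment: Sequence[EnrichmentRecord] = ()
    metrics: pd.DataFrame | None = None
    config_echo: Mapping[str, str] = field(default_factory=dict)
    seed: int | None = None
    tables: Mapping[str, Path] = field(default_factory=dict)

    @property
    def caller_summaries(self) -> list[dict]:
        return [summarize_caller(cs) for cs in sorted(self.callsets, key=lambda c: c.caller)]


def _table(headers: list[str], rows: list[list[str]]) -> str:
    head = "".join(f"<th>{html.escape(h)}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in rows
    )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return "NA"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def render_html(bundle: ReportBundle) -> str:
    """Render the report page as a single self-contained HTML string."""
    parts: list[str] = []
    parts.append(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>CNV consensus report — {html.escape(bundle.sample)}</title>"
        "<style>"
        "body{font-family:sans-serif;margin:2em;max-width:70em}"
        "table{border-collapse:collapse;margin:1em 0}"
        "th,td{border:1px solid #999;padding:0.25em 0.6em;text-align:right}"
        "th{background:#eee}td:first-child,th:first-child{text-align:left}"
        "h2{border-bottom:1px solid #ccc;padding-bottom:0.2em}"
        "</style></head><body>"
    )
    parts.append(f"<h1>CNV consensus report — sample {html.escape(bundle.sample)}</h1>")
    parts.append(
        f"<p>cnvconsensus {html.escape(__version__)}"
        + (f", seed {bundle.seed}" if bundle.seed is not None else "")
        + "</p>"
    )

    if bundle.config_echo:
        parts.append("<h2>Configuration</h2>")
        parts.append(
            _table(["key", "value"], [[k, v] for k, v in sorted(bundle.config_echo.items())])
        )

    parts.append("<h2>Per-caller summary</h2>")
    rows = []
    for s in bundle.caller_summaries:
        t = s["total"]
        rows.append(
            [s["caller"], t["gain_count"], t["loss_count"], t["gain_bp"], t["loss_bp"]]
        )
    parts.append(_table(["caller", "gains", "losses", "gain bp", "loss bp"], rows))

    for s in bundle.caller_summaries:
        parts.append(f"<h3>{html.escape(s['caller'])} per chromosome</h3>")
        rows = [
            [chrom, d["gain_count"], d["loss_count"], d["gain_bp"], d["loss_bp"]]
            for chrom, d in s["per_chromosome"].items()
        ]
        parts.append(_table(["chrom", "gains", "losses", "gain bp", "loss bp"], rows))

    if bundle.consensus is not None:
        parts.append("<h2>Caller-sharing (Venn) counts</h2>")
        rows = []
        for (subset, direction), (count, bp) in sorted(
            bundle.consensus.venn_counts.items(),
            key=lambda kv: (len(kv[0][0]), ",".join(sorted(kv[0][0])), kv[0][1].value),
        ):
            rows.append([",".join(sorted(subset)), direction.value, count, bp])
        parts.append(_table(["callers", "direction", "regions", "bp"], rows))

        parts.append("<h2>Consensus segments</h2>")
        rows = [
            [
                seg.interval.chrom,
                seg.interval.start,
                seg.interval.end,
                seg.direction.value,
                seg.multiplicity_class,
                ",".join(sorted(seg.supporting_callers)),
            ]
            for seg in bundle.consensus.segments
        ]
        parts.append(
            _table(["chrom", "start", "end", "direction", "class", "callers"], rows)
        )

    if bundle.gene_assignments:
        parts.append("<h2>Genes in CNV regions</h2>")
        rows = [
            [a.gene_id, a.multiplicity_class, a.direction.value,
             _fmt(a.coverage_fraction), ",".join(sorted(a.supporting_callers))]
            for a in bundle.gene_assignments
        ]
        parts.append(
            _table(["gene", "class", "direction", "coverage", "callers"], rows)
        )

    if bundle.enrichment:
        parts.append("<h2>Term enrichment (one-sided Fisher)</h2>")
        rows = [
            [r.term_id, r.catalog_name, r.a, r.b, r.c, r.d,
             _fmt(r.odds_ratio), _fmt(r.p_value), _fmt(r.p_adjusted)]
            for r in bundle.enrichment
        ]
        parts.append(
            _table(["term", "catalog", "a", "b", "c", "d", "OR", "p", "p (BH)"], rows)
        )

    if bundle.metrics is not None and len(bundle.metrics):
        parts.append("<h2>Benchmark vs truth</h2>")
        rows = [
            [r["call_set"], int(r["tp_bp"]), int(r["fp_bp"]), int(r["fn_bp"]),
             _fmt(None if pd.isna(r["tpr"]) else float(r["tpr"])),
             _fmt(None if pd.isna(r["fdr"]) else float(r["fdr"])),
             _fmt(None if pd.isna(r["precision"]) else float(r["precision"]))]
            for _, r in bundle.metrics.iterrows()
        ]
        parts.append(
            _table(["call set", "TP bp", "FP bp", "FN bp", "TPR", "FDR", "precision"], rows)
        )

    parts.append("</body></html>")
    return "".join(parts)
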