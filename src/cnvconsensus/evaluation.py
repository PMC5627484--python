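"""Base-level benchmarking of call sets against truth CNV profiles.

Scoring is direction-aware and counted per (base x direction slot): every
assayed base contributes one GAIN slot and one LOSS slot.  A slot is TP
when call and truth both cover the base in that direction, FP when only
the call does, FN when only the truth does, and TN otherwise, so
tp + fp + fn + tn == 2 x assayed bp always holds and a base where the
call says GAIN but the truth says LOSS is charged as both an FP (for the
call) and an FN (for the missed truth).  Copy-number magnitude is ignored
— only the gain/loss direction is scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import ConsensusResult, footprint
from .core import (
    CallSet,
    CnvCall,
    Direction,
    GenomicInterval,
    intersect_intervals,
    merge_intervals,
    normalize_callset,
    total_bp,
)

__all__ = ["TruthProfile", "Metrics", "confusion_counts", "evaluate_thresholds", "sum_counts"]

DirectionalRegions = Mapping[Direction, Sequence[GenomicInterval]]


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth CNV events for one sample (non-overlapping per direction)."""

    sample: str
    events: tuple[CnvCall, ...]

    @classmethod
    def from_calls(cls, calls: Sequence[CnvCall], sample: str) -> "TruthProfile":
        cs = normalize_callset(calls, caller="truth", sample=sample)
        return cls(sample=sample, events=cs.calls)

    def regions(self, direction: Direction) -> list[GenomicInterval]:
        return merge_intervals(
            e.interval for e in self.events if e.direction == direction
        )


@dataclass(frozen=True)
class Metrics:
    """Base-level confusion counts with derived TPR / FDR / precision.

    The ratio properties return ``None`` when their denominator is zero
    (no calls, or no truth); they are reported as NA downstream, never 0.
    """

    tp_bp: int
    fp_bp: int
    fn_bp: int
    tn_bp: int

    @property
    def tpr(self) -> float | None:
        denom = self.tp_bp + self.fn_bp
        return self.tp_bp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp_bp + self.fp_bp
        return self.tp_bp / denom if denom else None

    @property
    def fdr(self) -> float | None:
        denom = self.tp_bp + self.fp_bp
        return self.fp_bp / denom if denom else None


def confusion_counts(
    called: DirectionalRegions,
    truth: TruthProfile,
    assay_space: Sequence[GenomicInterval],
) -> Metrics:
    """Score called regions against a truth profile inside an assay space.

    ``called`` maps each direction to an interval set (a single caller's
    footprint or a consensus footprint).  All inputs are clipped to the
    assay space before counting.
    """
    assay = merge_intervals(assay_space)
    if not assay:
        raise ValueError("assay space is empty")
    assay_bp = total_bp(assay)

    tp = fp = fn = 0
    for direction in (Direction.GAIN, Direction.LOSS):
        call_iv = intersect_intervals(called.get(direction, []), assay)
        truth_iv = intersect_intervals(truth.regions(direction), assay)
        both = total_bp(intersect_intervals(call_iv, truth_iv))
        tp += both
        fp += total_bp(call_iv) - both
        fn += total_bp(truth_iv) - both
    tn = 2 * assay_bp - tp - fp - fn
    return Metrics(tp_bp=tp, fp_bp=fp, fn_bp=fn, tn_bp=tn)


def sum_counts(metrics: Iterable[Metrics]) -> Metrics:
    """Pool confusion counts across samples (micro-average)."""
    tp = fp = fn = tn = 0
    for m in metrics:
        tp += m.tp_bp
        fp += m.fp_bp
        fn += m.fn_bp
        tn += m.tn_bp
    return Metrics(tp_bp=tp, fp_bp=fp, fn_bp=fn, tn_bp=tn)


def _metrics_row(label: str, sample: str, m: Metrics) -> dict:
    return {
        "sample": sample,
        "call_set": label,
        "tp_bp": m.tp_bp,
        "fp_bp": m.fp_bp,
        "fn_bp": m.fn_bp,
        "tn_bp": m.tn_bp,
        "tpr": m.tpr,
        "fdr": m.fdr,
        "precision": m.precision,
    }


def evaluate_thresholds(
    callsets: Sequence[CallSet],
    truth: TruthProfile,
    assay_space: Sequence[GenomicInterval],
    consensus: ConsensusResult | None = None,
) -> pd.DataFrame:
    """Metrics table: one row per caller, one per consensus threshold k=1..N.

    The consensus row at threshold k scores the merged footprint of all
    segments supported by >= k callers.  A prebuilt consensus may be passed
    to avoid recomputation; otherwise it is built here.
    """
    from .consensus import build_consensus

    if consensus is None:
        consensus = build_consensus(callsets)
    rows = []
    for cs in sorted(callsets, key=lambda c: c.caller):
        called = {d: cs.footprint(d) for d in (Direction.GAIN, Direction.LOSS)}
        rows.append(
            _metrics_row(cs.caller, truth.sample, confusion_counts(called, truth, assay_space))
        )
    for k in range(1, len(callsets) + 1):
        called = footprint(consensus, min_callers=k)
        rows.append(
            _metrics_row(
                f"consensus>={k}",
                truth.sample,
                confusion_counts(called, truth, assay_space),
            )
        )
    return pd.DataFrame(rows)
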