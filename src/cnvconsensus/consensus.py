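"""Caller-multiplicity consensus over CNV call sets.

The genome is partitioned, per direction, at every breakpoint contributed
by any caller; each atomic piece carries exactly the set of callers whose
call covers it, and maximal runs with identical supporting sets and
per-caller copy numbers are re-merged.  The number of supporters of a
piece — its multiplicity — names the sharing class (unique / double /
triple / tetrad for 1..4 callers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    CallSet,
    ConsensusSegment,
    Direction,
    GenomicInterval,
    MalformedInputError,
    chrom_sort_key,
    merge_intervals,
)

__all__ = [
    "ConsensusResult",
    "build_consensus",
    "filter_min_callers",
    "class_regions",
    "footprint",
]

VennKey = tuple[frozenset, Direction]


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus segmentation for one sample.

    ``segments`` are non-overlapping within each direction and sorted by
    (chrom, start); ``venn_counts`` maps (caller subset, direction) to
    (number of maximal regions, total bp) with exactly that supporting set.
    """

    segments: tuple[ConsensusSegment, ...]
    callers: tuple[str, ...]
    venn_counts: Mapping[VennKey, tuple[int, int]]
    sample: str = ""

    def max_multiplicity(self) -> int:
        return len(self.callers)


def _segment_sort_key(seg: ConsensusSegment):
    return (chrom_sort_key(seg.interval.chrom), seg.interval.start, seg.direction.value)


def _venn_from_segments(
    segments: Iterable[ConsensusSegment],
) -> dict[VennKey, tuple[int, int]]:
    venn: dict[VennKey, tuple[int, int]] = {}
    for seg in segments:
        key = (seg.supporting_callers, seg.direction)
        count, bp = venn.get(key, (0, 0))
        venn[key] = (count + 1, bp + seg.interval.length())
    return venn


def build_consensus(
    callsets: Sequence[CallSet], min_segment_bp: int = 1
) -> ConsensusResult:
    """Partition all callers' calls into maximal constant-support segments.

    Directions are stratified: a gain and a loss never co-support a shared
    segment even when they overlap positionally.  Copy-number agreement is
    not required for sharing; each supporter's own copy number on the piece
    is carried in ``per_caller_cn``.  Segments shorter than
    ``min_segment_bp`` (default 1, i.e. keep everything down to 1-bp
    slivers) are dropped after maximal merging.

    Raises on mixed samples or duplicate caller names.
    """
    if not callsets:
        raise ValueError("build_consensus needs >= 1 call set")
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise MalformedInputError(f"mixed samples in consensus input: {sorted(samples)}")
    callers = [cs.caller for cs in callsets]
    if len(set(callers)) != len(callers):
        raise MalformedInputError(f"duplicate caller names: {callers}")
    sample = callsets[0].sample

    # canonical caller order keeps results independent of input order
    caller_order = tuple(sorted(callers))

    segments: list[ConsensusSegment] = []
    for direction in (Direction.GAIN, Direction.LOSS):
        # calls per chromosome across all callers
        per_chrom: dict[str, list] = {}
        for cs in callsets:
            for call in cs.calls:
                if call.direction != direction:
                    continue
                per_chrom.setdefault(call.interval.chrom, []).append(call)
        for chrom in sorted(per_chrom, key=chrom_sort_key):
            calls = per_chrom[chrom]
            cuts = sorted({c.interval.start for c in calls} | {c.interval.end for c in calls})
            pieces: list[tuple[int, int, frozenset, dict]] = []
            for lo, hi in zip(cuts, cuts[1:]):
                cover = [
                    c for c in calls if c.interval.start <= lo and c.interval.end >= hi
                ]
                if not cover:
                    continue
                support = frozenset(c.caller for c in cover)
                cn_map = {c.caller: c.copy_number for c in cover}
                pieces.append((lo, hi, support, cn_map))
            # re-merge maximal runs with identical label and copy numbers
            for lo, hi, support, cn_map in pieces:
                if (
                    segments
                    and segments[-1].direction == direction
                    and segments[-1].interval.chrom == chrom
                    and segments[-1].interval.end == lo
                    and segments[-1].supporting_callers == support
                    and dict(segments[-1].per_caller_cn) == cn_map
                ):
                    prev = segments.pop()
                    segments.append(
                        ConsensusSegment(
                            interval=GenomicInterval(chrom, prev.interval.start, hi),
                            direction=direction,
                            supporting_callers=support,
                            per_caller_cn=cn_map,
                        )
                    )
                else:
                    segments.append(
                        ConsensusSegment(
                            interval=GenomicInterval(chrom, lo, hi),
                            direction=direction,
                            supporting_callers=support,
                            per_caller_cn=cn_map,
                        )
                    )

    if min_segment_bp > 1:
        segments = [s for s in segments if s.interval.length() >= min_segment_bp]
    segments.sort(key=_segment_sort_key)
    return ConsensusResult(
        segments=tuple(segments),
        callers=caller_order,
        venn_counts=_venn_from_segments(segments),
        sample=sample,
    )


def filter_min_callers(result: ConsensusResult, min_callers: int) -> ConsensusResult:
    """Keep only segments supported by at least ``min_callers`` callers.

    Venn counts are recomputed on the retained set.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    kept = tuple(s for s in result.segments if s.multiplicity >= min_callers)
    return ConsensusResult(
        segments=kept,
        callers=result.callers,
        venn_counts=_venn_from_segments(kept),
        sample=result.sample,
    )


def class_regions(
    result: ConsensusResult, k: int
) -> dict[Direction, list[GenomicInterval]]:
    """Merged regions supported by exactly ``k`` callers, per direction.

    Adjacent (bookended) exactly-k segments are coalesced even when their
    supporting sets differ.
    """
    if k < 1:
        raise ValueError("multiplicity class must be >= 1")
    out: dict[Direction, list[GenomicInterval]] = {}
    for direction in (Direction.GAIN, Direction.LOSS):
        out[direction] = merge_intervals(
            s.interval
            for s in result.segments
            if s.direction == direction and s.multiplicity == k
        )
    return out


def footprint(
    result: ConsensusResult, min_callers: int = 1
) -> dict[Direction, list[GenomicInterval]]:
    """Merged regions supported by at least ``min_callers``, per direction."""
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    out: dict[Direction, list[GenomicInterval]] = {}
    for direction in (Direction.GAIN, Direction.LOSS):
        out[direction] = merge_intervals(
            s.interval
            for s in result.segments
            if s.direction == direction and s.multiplicity >= min_callers
        )
    return out
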