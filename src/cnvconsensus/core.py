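"""Domain types and exact genomic-interval algebra.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval ``[start, end)`` covers the integer bases ``start .. end-1``.
Copy number is measured against a diploid baseline of 2 — copy number
above 2 is a gain, below 2 a loss; a record at exactly 2 carries no
variation and is rejected at the type level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Direction",
    "GenomicInterval",
    "CnvCall",
    "CallSet",
    "ConsensusSegment",
    "GeneModel",
    "MalformedInputError",
    "direction_for_copy_number",
    "interval_overlap",
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "total_bp",
    "chrom_sort_key",
    "normalize_callset",
]

DIPLOID_CN = 2


class MalformedInputError(ValueError):
    """Raised when an input violates the call-set contract (e.g. a caller
    reports overlapping gain and loss at the same locus)."""


class Direction(str, Enum):
    """Direction of a copy-number change relative to the diploid baseline."""

    GAIN = "gain"
    LOSS = "loss"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def direction_for_copy_number(copy_number: int) -> Direction:
    """Classify a copy number as GAIN (>2) or LOSS (<2).

    Raises ``ValueError`` for the diploid baseline (2) or negative values.
    """
    if copy_number < 0:
        raise ValueError(f"copy number must be >= 0, got {copy_number}")
    if copy_number == DIPLOID_CN:
        raise ValueError("copy number 2 is the diploid baseline, not a CNV")
    return Direction.GAIN if copy_number > DIPLOID_CN else Direction.LOSS


_CHROM_RE = re.compile(r"^(chr)?(\d+|[A-Za-z]+)$")


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX < chrY.

    Numeric chromosomes sort numerically before alphabetic ones; unknown
    names fall back to lexicographic order after the named set.
    """
    m = _CHROM_RE.match(chrom)
    body = m.group(2) if m else chrom
    if body.isdigit():
        return (0, int(body))
    return (1, body.upper())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:[{self.start}, {self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:[{self.start}, {self.end})"


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if on different chromosomes).

    Symmetric; half-open adjacency ([0,10) vs [10,20)) overlaps by 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class CnvCall:
    """One caller's called segment: interval + copy number + direction."""

    interval: GenomicInterval
    copy_number: int
    direction: Direction
    caller: str
    sample: str

    def __post_init__(self) -> None:
        expected = direction_for_copy_number(self.copy_number)
        if expected != self.direction:
            raise ValueError(
                f"copy number {self.copy_number} implies {expected.value}, "
                f"not {self.direction.value}"
            )

    @classmethod
    def from_copy_number(
        cls, interval: GenomicInterval, copy_number: int, caller: str, sample: str
    ) -> "CnvCall":
        return cls(
            interval=interval,
            copy_number=copy_number,
            direction=direction_for_copy_number(copy_number),
            caller=caller,
            sample=sample,
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic footprint; ``gene_id`` is unique per catalog."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ConsensusSegment:
    """Maximal genomic run with a constant set of supporting callers.

    ``multiplicity`` (the number of supporters) names the sharing class:
    1 -> unique, 2 -> double, 3 -> triple, 4 -> tetrad.
    """

    interval: GenomicInterval
    direction: Direction
    supporting_callers: frozenset[str]
    per_caller_cn: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.supporting_callers:
            raise ValueError("a consensus segment needs >= 1 supporting caller")
        if set(self.per_caller_cn) != set(self.supporting_callers):
            raise ValueError("per_caller_cn keys must equal supporting_callers")
        # freeze the map so the dataclass stays hashable-safe in practice
        object.__setattr__(self, "per_caller_cn", dict(self.per_caller_cn))

    @property
    def multiplicity(self) -> int:
        return len(self.supporting_callers)

    @property
    def multiplicity_class(self) -> str:
        names = {1: "unique", 2: "double", 3: "triple", 4: "tetrad"}
        return names.get(self.multiplicity, f"{self.multiplicity}-caller")


@dataclass(frozen=True)
class CallSet:
    """One caller's normalized calls for one sample.

    Within a direction the intervals on a chromosome are non-overlapping
    and the calls are sorted by (chrom, start).
    """

    caller: str
    sample: str
    calls: tuple[CnvCall, ...] = ()

    def footprint(self, direction: Direction) -> list[GenomicInterval]:
        """Merged interval set covered by this caller in one direction."""
        return merge_intervals(
            [c.interval for c in self.calls if c.direction == direction]
        )


# ---------------------------------------------------------------------------
# Interval-set algebra.  Interval sets are plain lists of GenomicInterval;
# the merge/intersect/subtract primitives always return disjoint intervals
# sorted by (chrom, start) under the natural chromosome order.
# ---------------------------------------------------------------------------


def _sorted(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended pieces are coalesced."""
    out: list[GenomicInterval] = []
    for iv in _sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-wise intersection of two interval sets."""
    a_m, b_m = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a_m) and j < len(b_m):
        x, y = a_m[i], b_m[j]
        kx, ky = chrom_sort_key(x.chrom), chrom_sort_key(y.chrom)
        if kx < ky:
            i += 1
            continue
        if ky < kx:
            j += 1
            continue
        lo, hi = max(x.start, y.start), min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in ``a`` not covered by ``b``."""
    a_m, b_m = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    j = 0
    for x in a_m:
        kx = chrom_sort_key(x.chrom)
        cur = x.start
        while j < len(b_m) and (
            chrom_sort_key(b_m[j].chrom) < kx
            or (b_m[j].chrom == x.chrom and b_m[j].end <= cur)
        ):
            j += 1
        k = j
        while k < len(b_m) and b_m[k].chrom == x.chrom and b_m[k].start < x.end:
            if b_m[k].start > cur:
                out.append(GenomicInterval(x.chrom, cur, b_m[k].start))
            cur = max(cur, b_m[k].end)
            k += 1
        if cur < x.end:
            out.append(GenomicInterval(x.chrom, cur, x.end))
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered (after merging overlaps)."""
    return sum(iv.length() for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# Call-set normalization.
# ---------------------------------------------------------------------------


def normalize_callset(
    raw_calls: Sequence[CnvCall],
    caller: str | None = None,
    sample: str | None = None,
) -> CallSet:
    """Normalize one caller's raw calls into a canonical :class:`CallSet`.

    Overlapping or bookended same-direction calls are merged into one call,
    keeping the extreme copy number (maximum for gains, minimum for losses —
    the strongest event wins).  Overlapping calls of opposite direction are a
    contract violation and raise :class:`MalformedInputError` naming the loci.

    ``caller``/``sample`` may be given explicitly (required for an empty
    input); with calls present they must agree with the calls themselves.
    """
    callers = {c.caller for c in raw_calls}
    samples = {c.sample for c in raw_calls}
    if len(callers) > 1 or len(samples) > 1:
        raise MalformedInputError(
            f"normalize_callset expects one caller/sample, got callers={sorted(callers)} "
            f"samples={sorted(samples)}"
        )
    if raw_calls:
        inferred_caller, inferred_sample = raw_calls[0].caller, raw_calls[0].sample
        if caller is not None and caller != inferred_caller:
            raise MalformedInputError(
                f"caller mismatch: {caller!r} vs calls' {inferred_caller!r}"
            )
        if sample is not None and sample != inferred_sample:
            raise MalformedInputError(
                f"sample mismatch: {sample!r} vs calls' {inferred_sample!r}"
            )
        caller, sample = inferred_caller, inferred_sample
    if caller is None or sample is None:
        raise ValueError("caller and sample are required for an empty call list")

    # Opposite-direction overlap check: strictly overlapping (not merely
    # bookended) gain/loss pairs on one chromosome are malformed input.
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in raw_calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom, calls in by_chrom.items():
        calls.sort(key=lambda c: (c.interval.start, c.interval.end))
        active_end = {Direction.GAIN: -1, Direction.LOSS: -1}
        active_iv: dict[Direction, GenomicInterval | None] = {
            Direction.GAIN: None,
            Direction.LOSS: None,
        }
        for c in calls:
            other = Direction.LOSS if c.direction == Direction.GAIN else Direction.GAIN
            if c.interval.start < active_end[other]:
                raise MalformedInputError(
                    f"caller {caller!r} reports overlapping gain and loss: "
                    f"{active_iv[other]} vs {c.interval}"
                )
            if c.interval.end > active_end[c.direction]:
                active_end[c.direction] = c.interval.end
                active_iv[c.direction] = c.interval

    merged: list[CnvCall] = []
    for direction in (Direction.GAIN, Direction.LOSS):
        per_dir = [c for c in raw_calls if c.direction == direction]
        per_dir.sort(key=lambda c: (chrom_sort_key(c.interval.chrom), c.interval.start))
        run: list[CnvCall] = []
        for c in per_dir:
            if (
                run
                and c.interval.chrom == run[-1].interval.chrom
                and c.interval.start <= max(x.interval.end for x in run)
            ):
                run.append(c)
            else:
                if run:
                    merged.append(_merge_run(run, direction, caller, sample))
                run = [c]
        if run:
            merged.append(_merge_run(run, direction, caller, sample))

    merged.sort(key=lambda c: (chrom_sort_key(c.interval.chrom), c.interval.start))
    return CallSet(caller=caller, sample=sample, calls=tuple(merged))


def _merge_run(
    run: list[CnvCall], direction: Direction, caller: str, sample: str
) -> CnvCall:
    start = min(c.interval.start for c in run)
    end = max(c.interval.end for c in run)
    cns = [c.copy_number for c in run]
    cn = max(cns) if direction == Direction.GAIN else min(cns)
    return CnvCall(
        interval=GenomicInterval(run[0].interval.chrom, start, end),
        copy_number=cn,
        direction=direction,
        caller=caller,
        sample=sample,
    )
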