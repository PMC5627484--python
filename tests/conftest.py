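"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval algebra: they
label every base of a small coordinate space explicitly (numpy boolean
masks) and re-derive consensus labels / confusion counts from those
per-base labels, so they can check the sweep-based implementations
against an independent route.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from cnvconsensus.core import (
    CallSet,
    CnvCall,
    Direction,
    GenomicInterval,
    normalize_callset,
)

CHROMS = ("chr1", "chr2")


def make_call(chrom, start, end, cn, caller="A", sample="s") -> CnvCall:
    return CnvCall.from_copy_number(GenomicInterval(chrom, start, end), cn, caller, sample)


# ---------------------------------------------------------------------------
# Random small instances for oracle comparisons.
# ---------------------------------------------------------------------------


def random_callsets(
    rng: np.random.Generator,
    max_callers: int = 4,
    max_calls: int = 30,
    coord_max: int = 100_000,
    sample: str = "s",
) -> list[CallSet]:
    """Random normalized call sets on a small coordinate space.

    Same-caller gain/loss conflicts are resolved before normalization
    (losses overlapping a gain of the same caller are dropped) since the
    call-set contract forbids them.
    """
    n_callers = int(rng.integers(1, max_callers + 1))
    callsets = []
    for i in range(n_callers):
        caller = f"C{i}"
        n_calls = int(rng.integers(0, max_calls + 1))
        raw: list[CnvCall] = []
        for _ in range(n_calls):
            start = int(rng.integers(0, coord_max - 1))
            length = int(rng.integers(1, max(2, coord_max // 10)))
            end = min(coord_max, start + length)
            chrom = CHROMS[int(rng.integers(0, len(CHROMS)))]
            cn = int(rng.choice([0, 1, 3, 4, 5, 8]))
            cand = make_call(chrom, start, end, cn, caller, sample)
            clash = any(
                k.interval.chrom == cand.interval.chrom
                and k.direction != cand.direction
                and k.interval.start < cand.interval.end
                and cand.interval.start < k.interval.end
                for k in raw
            )
            if not clash:
                raw.append(cand)
        callsets.append(normalize_callset(raw, caller=caller, sample=sample))
    return callsets


# ---------------------------------------------------------------------------
# Per-base consensus oracle.
# ---------------------------------------------------------------------------


def per_base_consensus(
    callsets: list[CallSet], coord_max: int
) -> dict[tuple[str, Direction], list[tuple[int, int, frozenset]]]:
    """Label every base with its covering-caller set and recompress.

    Returns, per (chrom, direction), maximal runs (start, end, supporters)
    with a constant non-empty supporting set.
    """
    callers = sorted(cs.caller for cs in callsets)
    bit = {c: 1 << i for i, c in enumerate(callers)}
    out: dict[tuple[str, Direction], list[tuple[int, int, frozenset]]] = {}
    for chrom in CHROMS:
        for direction in (Direction.GAIN, Direction.LOSS):
            mask = np.zeros(coord_max, dtype=np.int64)
            for cs in callsets:
                for c in cs.calls:
                    if c.interval.chrom == chrom and c.direction == direction:
                        mask[c.interval.start : c.interval.end] |= bit[cs.caller]
            runs: list[tuple[int, int, frozenset]] = []
            cuts = np.flatnonzero(np.diff(mask)) + 1
            bounds = np.concatenate([[0], cuts, [coord_max]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                value = int(mask[lo])
                if value:
                    support = frozenset(c for c in callers if value & bit[c])
                    runs.append((int(lo), int(hi), support))
            out[(chrom, direction)] = runs
    return out


def segments_as_runs(result, chrom, direction):
    """Flatten ConsensusResult segments on one (chrom, direction) into
    (start, end, supporters) runs, re-merging bookended pieces with the
    same supporting set (the oracle cannot see copy-number splits)."""
    runs: list[tuple[int, int, frozenset]] = []
    for s in result.segments:
        if s.interval.chrom != chrom or s.direction != direction:
            continue
        item = (s.interval.start, s.interval.end, s.supporting_callers)
        if runs and runs[-1][1] == item[0] and runs[-1][2] == item[2]:
            runs[-1] = (runs[-1][0], item[1], item[2])
        else:
            runs.append(item)
    return runs


# ---------------------------------------------------------------------------
# Exact hypergeometric tail oracle (rational arithmetic).
# ---------------------------------------------------------------------------


def hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), computed by
    direct enumeration with exact rationals."""
    big_n, big_k, n = a + b + c + d, a + c, a + b
    denom = math.comb(big_n, n)
    total = Fraction(0)
    for k in range(a, min(big_k, n) + 1):
        total += Fraction(math.comb(big_k, k) * math.comb(big_n - big_k, n - k), denom)
    return total


# ---------------------------------------------------------------------------
# Per-base confusion-count oracle.
# ---------------------------------------------------------------------------


def per_base_confusion(called, truth, assay, coord_max: int):
    """Enumerate every (base x direction slot) inside the assay space."""
    tp = fp = fn = tn = 0
    for chrom in CHROMS:
        assay_mask = np.zeros(coord_max, dtype=bool)
        for iv in assay:
            if iv.chrom == chrom:
                assay_mask[iv.start : iv.end] = True
        for direction in (Direction.GAIN, Direction.LOSS):
            call_mask = np.zeros(coord_max, dtype=bool)
            for iv in called.get(direction, []):
                if iv.chrom == chrom:
                    call_mask[iv.start : iv.end] = True
            truth_mask = np.zeros(coord_max, dtype=bool)
            for e in truth.events:
                if e.interval.chrom == chrom and e.direction == direction:
                    truth_mask[e.interval.start : e.interval.end] = True
            call_mask &= assay_mask
            truth_mask &= assay_mask
            tp += int(np.sum(call_mask & truth_mask))
            fp += int(np.sum(call_mask & ~truth_mask))
            fn += int(np.sum(~call_mask & truth_mask))
            tn += int(np.sum(assay_mask & ~call_mask & ~truth_mask))
    return tp, fp, fn, tn


@pytest.fixture
def rng():
    return np.random.default_rng(20260131)
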