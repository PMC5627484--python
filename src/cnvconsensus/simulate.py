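"""Seeded benchmark simulator: truth CNV profiles and noisy per-caller calls.

The generator emulates the benchmark design used to compare single-caller
and integrated CNV calling: a panel of simulated tumor samples, each
carrying a fixed number of CNV events with copy numbers from 1 to 20
(excluding the diploid 2) and sizes from 500 kb to 4.5 Mb, plus four
synthetic caller profiles whose detection probability depends on event
size — mirroring the reported behavioral biases that one tool favors
large CNVs, one medium-size CNVs and two smaller CNVs.

The simulator models caller OUTPUTS (segment lists), not sequencing
reads: detection is a size-dependent Bernoulli draw, breakpoints get
Gaussian jitter, copy numbers are occasionally perturbed without crossing
the gain/loss boundary, and false positives arrive as a Poisson process
along the genome, avoiding the truth footprint.

All randomness derives from a single seed through stable per-sample /
per-caller labels, so adding a caller or sample never changes any other
stream's draws.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import TermCatalog
from .core import (
    CallSet,
    CnvCall,
    Direction,
    GeneModel,
    GenomicInterval,
    chrom_sort_key,
    normalize_callset,
)
from .evaluation import TruthProfile

__all__ = [
    "GenomeSpec",
    "TruthSpec",
    "CallerNoiseProfile",
    "default_noise_profiles",
    "simulate_truth",
    "simulate_calls",
    "simulate_genes",
    "simulate_terms",
]

DEFAULT_COPY_NUMBERS = tuple(cn for cn in range(1, 21) if cn != 2)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Child generator derived from (seed, label); stable across runs."""
    digest = hashlib.sha256(label.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *words]))


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths for the simulated genome."""

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 60_000_000, "chr3": 60_000_000}
    )

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def total_bp(self) -> int:
        return sum(self.chromosomes.values())

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, 0, l)
            for c, l in sorted(self.chromosomes.items(), key=lambda kv: chrom_sort_key(kv[0]))
        ]


@dataclass(frozen=True)
class TruthSpec:
    """Panel design: how many samples, and what CNVs each one carries."""

    n_samples: int = 13
    cnvs_per_sample: int = 10
    copy_number_range: tuple[int, ...] = DEFAULT_COPY_NUMBERS
    size_range_bp: tuple[int, int] = (500_000, 4_500_000)
    min_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if 2 in self.copy_number_range:
            raise ValueError("copy_number_range must exclude the diploid baseline 2")
        lo, hi = self.size_range_bp
        if not (0 < lo <= hi):
            raise ValueError(f"bad size range {self.size_range_bp}")


@dataclass(frozen=True)
class CallerNoiseProfile:
    """Output-level noise model for one synthetic caller.

    ``detection_steps`` is a piecewise-constant detection probability over
    event size: a sorted tuple of (size upper bound in bp, probability);
    the last bound should be ``inf``.
    """

    caller: str
    detection_steps: tuple[tuple[float, float], ...]
    breakpoint_jitter_sd_bp: float = 10_000.0
    fp_rate_per_mb: float = 0.02
    fp_size_range_bp: tuple[int, int] = (50_000, 500_000)
    cn_error_prob: float = 0.1

    def __post_init__(self) -> None:
        for _, p in self.detection_steps:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"detection probability {p} outside [0, 1]")
        if self.breakpoint_jitter_sd_bp < 0:
            raise ValueError("jitter SD must be >= 0")
        if not (0.0 <= self.cn_error_prob <= 1.0):
            raise ValueError("cn_error_prob outside [0, 1]")

    def detection_prob(self, size_bp: int) -> float:
        for bound, p in self.detection_steps:
            if size_bp <= bound:
                return p
        return self.detection_steps[-1][1]


def default_noise_profiles() -> list[CallerNoiseProfile]:
    """Four synthetic callers with the qualitative size biases of the
    integrated tools: one favoring large events, one medium, two small.

    Step bounds split the truth size range (0.5-4.5 Mb) into small
    (<1.5 Mb), medium (1.5-3 Mb) and large (>3 Mb) tiers.
    """
    inf = math.inf
    return [
        CallerNoiseProfile(  # large-CNV specialist
            caller="excavator_like",
            detection_steps=((1_500_000, 0.50), (3_000_000, 0.75), (inf, 0.95)),
            breakpoint_jitter_sd_bp=20_000,
            fp_rate_per_mb=0.02,
        ),
        CallerNoiseProfile(  # medium-CNV specialist
            caller="adtex_like",
            detection_steps=((1_500_000, 0.65), (3_000_000, 0.90), (inf, 0.70)),
            breakpoint_jitter_sd_bp=15_000,
            fp_rate_per_mb=0.03,
        ),
        CallerNoiseProfile(  # small-CNV specialist, calls the most
            caller="exomecnv_like",
            detection_steps=((1_500_000, 0.90), (3_000_000, 0.70), (inf, 0.55)),
            breakpoint_jitter_sd_bp=10_000,
            fp_rate_per_mb=0.06,
        ),
        CallerNoiseProfile(  # small-CNV specialist
            caller="freec_like",
            detection_steps=((1_500_000, 0.85), (3_000_000, 0.65), (inf, 0.50)),
            breakpoint_jitter_sd_bp=12_000,
            fp_rate_per_mb=0.04,
        ),
    ]


def _sample_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_truth(
    genome: GenomeSpec, spec: TruthSpec, seed: int
) -> list[TruthProfile]:
    """Generate the truth panel: ``n_samples`` profiles of non-overlapping
    CNVs with pairwise gaps of at least ``min_gap_bp``.

    Fully reproducible from ``seed``; raises if placement is infeasible
    after bounded retries (the genome is too small for the demanded
    events plus gaps).
    """
    lo, hi = spec.size_range_bp
    max_chrom = max(genome.chromosomes.values())
    if hi > max_chrom:
        raise ValueError("largest permitted CNV exceeds every chromosome")
    chroms = sorted(genome.chromosomes, key=chrom_sort_key)
    lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    profiles: list[TruthProfile] = []
    for sample in _sample_ids(spec.n_samples):
        rng = _rng(seed, f"truth/{sample}")
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        events: list[CnvCall] = []
        for _ in range(spec.cnvs_per_sample):
            ok = False
            for _attempt in range(1000):
                size = int(rng.integers(lo, hi + 1))
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                chrom_len = genome.chromosomes[chrom]
                if chrom_len <= size:
                    continue
                start = int(rng.integers(0, chrom_len - size + 1))
                end = start + size
                gap = spec.min_gap_bp
                if any(start < e + gap and s - gap < end for s, e in placed[chrom]):
                    continue
                cn = int(rng.choice(spec.copy_number_range))
                events.append(
                    CnvCall.from_copy_number(
                        GenomicInterval(chrom, start, end), cn, "truth", sample
                    )
                )
                placed[chrom].append((start, end))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place {spec.cnvs_per_sample} CNVs with "
                    f"{spec.min_gap_bp} bp gaps in sample {sample}; "
                    "use a larger genome or fewer/smaller events"
                )
        events.sort(key=lambda e: (chrom_sort_key(e.interval.chrom), e.interval.start))
        profiles.append(TruthProfile(sample=sample, events=tuple(events)))
    return profiles


def simulate_calls(
    truth: TruthProfile,
    profiles: Sequence[CallerNoiseProfile],
    genome: GenomeSpec,
    seed: int,
) -> list[CallSet]:
    """Generate each synthetic caller's noisy call set for one sample."""
    if not profiles:
        raise ValueError("need >= 1 caller noise profile")
    truth_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in truth.events:
        truth_by_chrom.setdefault(e.interval.chrom, []).append(
            (e.interval.start, e.interval.end)
        )

    callsets: list[CallSet] = []
    for profile in profiles:
        rng = _rng(seed, f"calls/{truth.sample}/{profile.caller}")
        calls: list[CnvCall] = []

        for event in truth.events:
            size = event.interval.length()
            if rng.random() >= profile.detection_prob(size):
                continue
            chrom = event.interval.chrom
            chrom_len = genome.chromosomes[chrom]
            sd = profile.breakpoint_jitter_sd_bp
            start = event.interval.start + int(round(rng.normal(0, sd)))
            end = event.interval.end + int(round(rng.normal(0, sd)))
            start = min(max(start, 0), chrom_len - 1)
            end = min(max(end, start + 1), chrom_len)
            cn = event.copy_number
            if profile.cn_error_prob and rng.random() < profile.cn_error_prob:
                delta = int(rng.choice([-1, 1]))
                if event.direction == Direction.GAIN:
                    cn = max(3, cn + delta)
                else:
                    cn = min(1, max(0, cn + delta))
            calls.append(
                CnvCall.from_copy_number(
                    GenomicInterval(chrom, start, end), cn, profile.caller, truth.sample
                )
            )

        # false positives: Poisson along the genome, avoiding the truth footprint
        n_fp = int(rng.poisson(profile.fp_rate_per_mb * genome.total_bp() / 1e6))
        chroms = sorted(genome.chromosomes, key=chrom_sort_key)
        lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
        weights = lengths / lengths.sum()
        log_lo, log_hi = (math.log(b) for b in profile.fp_size_range_bp)
        for _ in range(n_fp):
            for _attempt in range(100):
                size = max(1, int(round(math.exp(rng.uniform(log_lo, log_hi)))))
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                chrom_len = genome.chromosomes[chrom]
                if chrom_len <= size:
                    continue
                start = int(rng.integers(0, chrom_len - size + 1))
                end = start + size
                if any(
                    start < e and s < end for s, e in truth_by_chrom.get(chrom, [])
                ):
                    continue
                gain = bool(rng.random() < 0.5)
                cn = int(rng.integers(3, 7)) if gain else int(rng.integers(0, 2))
                calls.append(
                    CnvCall.from_copy_number(
                        GenomicInterval(chrom, start, end), cn, profile.caller, truth.sample
                    )
                )
                break

        # drop opposite-direction self-overlaps a jittered caller can produce
        calls = _resolve_direction_conflicts(calls)
        callsets.append(
            normalize_callset(calls, caller=profile.caller, sample=truth.sample)
        )
    return callsets


def _resolve_direction_conflicts(calls: list[CnvCall]) -> list[CnvCall]:
    """Keep the earlier call when jitter makes a gain and a loss collide."""
    kept: list[CnvCall] = []
    for c in sorted(
        calls, key=lambda c: (chrom_sort_key(c.interval.chrom), c.interval.start)
    ):
        clash = any(
            k.interval.chrom == c.interval.chrom
            and k.direction != c.direction
            and k.interval.start < c.interval.end
            and c.interval.start < k.interval.end
            for k in kept
        )
        if not clash:
            kept.append(c)
    return kept


def simulate_genes(
    genome: GenomeSpec,
    n_genes: int = 400,
    size_range_bp: tuple[int, int] = (5_000, 200_000),
    seed: int = 0,
) -> list[GeneModel]:
    """Random non-overlapping gene models scattered over the genome."""
    rng = _rng(seed, "genes")
    chroms = sorted(genome.chromosomes, key=chrom_sort_key)
    lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    lo, hi = size_range_bp
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    i = 0
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 200:
        attempts += 1
        size = int(rng.integers(lo, hi + 1))
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        chrom_len = genome.chromosomes[chrom]
        if chrom_len <= size:
            continue
        start = int(rng.integers(0, chrom_len - size + 1))
        end = start + size
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        i += 1
        genes.append(GeneModel(f"G{i:04d}", GenomicInterval(chrom, start, end)))
    if len(genes) < n_genes:
        raise RuntimeError("could not place the requested number of genes")
    genes.sort(key=lambda g: (chrom_sort_key(g.interval.chrom), g.interval.start))
    return genes


def simulate_terms(
    genes: Sequence[GeneModel],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
    catalog_name: str = "simGO",
) -> TermCatalog:
    """Random gene-set catalog (GMT-like) drawn from the simulated genes."""
    rng = _rng(seed, f"terms/{catalog_name}")
    ids = [g.gene_id for g in genes]
    lo, hi = term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(1, n_terms + 1):
        k = int(rng.integers(lo, min(hi, len(ids)) + 1))
        members = rng.choice(len(ids), size=k, replace=False)
        terms[f"{catalog_name}:{t:04d}"] = (
            f"simulated term {t}",
            frozenset(ids[j] for j in members),
        )
    return TermCatalog(catalog_name=catalog_name, terms=terms)
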