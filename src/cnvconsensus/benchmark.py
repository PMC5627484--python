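"""Seeded single-vs-integrated benchmark study.

One scenario simulates a truth panel, generates every synthetic caller's
noisy call set per sample, and pools base-level confusion counts over
the panel — per individual caller and per consensus threshold k — so
the stability of integrated calling can be compared against any single
caller across replicate seeds.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .consensus import build_consensus, footprint
from .core import Direction
from .evaluation import Metrics, confusion_counts, sum_counts
from .simulate import (
    CallerNoiseProfile,
    GenomeSpec,
    TruthSpec,
    default_noise_profiles,
    simulate_calls,
    simulate_truth,
)

__all__ = ["benchmark_scenario", "benchmark_study"]


def benchmark_scenario(
    seed: int,
    genome: GenomeSpec | None = None,
    truth_spec: TruthSpec | None = None,
    profiles: Sequence[CallerNoiseProfile] | None = None,
) -> pd.DataFrame:
    """Run one seeded scenario and pool metrics over the whole panel.

    Returns one row per call set ("caller:<name>" or "consensus>=k") with
    pooled tp/fp/fn/tn bp and derived tpr/fdr/precision.
    """
    genome = genome or GenomeSpec()
    truth_spec = truth_spec or TruthSpec()
    profiles = list(profiles) if profiles is not None else default_noise_profiles()
    assay = genome.intervals()

    per_caller: dict[str, list[Metrics]] = {p.caller: [] for p in profiles}
    per_k: dict[int, list[Metrics]] = {k: [] for k in range(1, len(profiles) + 1)}
    for truth in simulate_truth(genome, truth_spec, seed):
        callsets = simulate_calls(truth, profiles, genome, seed)
        for cs in callsets:
            called = {d: cs.footprint(d) for d in (Direction.GAIN, Direction.LOSS)}
            per_caller[cs.caller].append(confusion_counts(called, truth, assay))
        consensus = build_consensus(callsets)
        for k in per_k:
            per_k[k].append(
                confusion_counts(footprint(consensus, k), truth, assay)
            )

    rows = []
    for caller in sorted(per_caller):
        m = sum_counts(per_caller[caller])
        rows.append(_row(seed, f"caller:{caller}", m))
    for k in sorted(per_k):
        m = sum_counts(per_k[k])
        rows.append(_row(seed, f"consensus>={k}", m))
    return pd.DataFrame(rows)


def _row(seed: int, label: str, m: Metrics) -> dict:
    return {
        "seed": seed,
        "call_set": label,
        "tp_bp": m.tp_bp,
        "fp_bp": m.fp_bp,
        "fn_bp": m.fn_bp,
        "tn_bp": m.tn_bp,
        "tpr": m.tpr,
        "fdr": m.fdr,
        "precision": m.precision,
    }


def benchmark_study(
    seeds: Sequence[int],
    genome: GenomeSpec | None = None,
    truth_spec: TruthSpec | None = None,
    profiles: Sequence[CallerNoiseProfile] | None = None,
) -> pd.DataFrame:
    """Concatenate :func:`benchmark_scenario` over replicate seeds."""
    return pd.concat(
        [benchmark_scenario(s, genome, truth_spec, profiles) for s in seeds],
        ignore_index=True,
    )
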