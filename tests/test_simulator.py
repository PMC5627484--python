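"""Simulator: determinism, panel shape, noise limits and recall calibration."""

import math

import pytest

from cnvconsensus.consensus import build_consensus, footprint
from cnvconsensus.core import Direction, subtract_intervals, total_bp
from cnvconsensus.evaluation import confusion_counts
from cnvconsensus.simulate import (
    CallerNoiseProfile,
    GenomeSpec,
    TruthSpec,
    default_noise_profiles,
    simulate_calls,
    simulate_genes,
    simulate_terms,
    simulate_truth,
)

GENOME = GenomeSpec()


class TestSimulateTruth:
    def test_default_panel_shape(self):
        """13 samples x 10 events, sizes in [500 kb, 4.5 Mb], copies in
        {1, 3..20}, pairwise gaps >= 1 Mb."""
        spec = TruthSpec()
        profiles = simulate_truth(GENOME, spec, seed=7)
        assert len(profiles) == 13
        for p in profiles:
            assert len(p.events) == 10
            for e in p.events:
                assert 500_000 <= e.interval.length() <= 4_500_000
                assert e.copy_number in set(range(1, 21)) - {2}
            by_chrom = {}
            for e in p.events:
                by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
            for ivs in by_chrom.values():
                ivs.sort(key=lambda iv: iv.start)
                for a, b in zip(ivs, ivs[1:]):
                    assert b.start - a.end >= 1_000_000

    def test_same_seed_reproduces_identical_profiles(self):
        spec = TruthSpec(n_samples=3)
        assert simulate_truth(GENOME, spec, seed=11) == simulate_truth(
            GENOME, spec, seed=11
        )
        assert simulate_truth(GENOME, spec, seed=11) != simulate_truth(
            GENOME, spec, seed=12
        )

    def test_zero_events_gives_empty_profiles(self):
        spec = TruthSpec(n_samples=2, cnvs_per_sample=0)
        profiles = simulate_truth(GENOME, spec, seed=1)
        assert all(p.events == () for p in profiles)

    def test_infeasible_placement_raises(self):
        tiny = GenomeSpec({"chr1": 6_000_000})
        spec = TruthSpec(n_samples=1, cnvs_per_sample=10)
        with pytest.raises(RuntimeError):
            simulate_truth(tiny, spec, seed=1)

    def test_oversized_events_rejected(self):
        tiny = GenomeSpec({"chr1": 1_000_000})
        with pytest.raises(ValueError):
            simulate_truth(tiny, TruthSpec(n_samples=1), seed=1)

    def test_baseline_copy_number_disallowed_in_spec(self):
        with pytest.raises(ValueError):
            TruthSpec(copy_number_range=(1, 2, 3))


def _noiseless(caller="perfect"):
    return CallerNoiseProfile(
        caller=caller,
        detection_steps=((math.inf, 1.0),),
        breakpoint_jitter_sd_bp=0.0,
        fp_rate_per_mb=0.0,
        cn_error_prob=0.0,
    )


def _deaf(caller="deaf"):
    return CallerNoiseProfile(
        caller=caller,
        detection_steps=((math.inf, 0.0),),
        fp_rate_per_mb=0.0,
    )


class TestSimulateCalls:
    def test_noiseless_limit_reproduces_truth_exactly(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=3)[0]
        (cs,) = simulate_calls(truth, [_noiseless()], GENOME, seed=3)
        got = [(c.interval, c.copy_number, c.direction) for c in cs.calls]
        want = [(e.interval, e.copy_number, e.direction) for e in truth.events]
        assert got == want

    def test_noiseless_pipeline_scores_perfectly_at_every_threshold(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=5)[0]
        profiles = [_noiseless(f"P{i}") for i in range(4)]
        callsets = simulate_calls(truth, profiles, GENOME, seed=5)
        res = build_consensus(callsets)
        for k in range(1, 5):
            m = confusion_counts(footprint(res, k), truth, GENOME.intervals())
            assert m.tpr == 1.0 and m.fdr == 0.0 and m.precision == 1.0

    def test_deaf_caller_calls_nothing(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=3)[0]
        (cs,) = simulate_calls(truth, [_deaf()], GENOME, seed=3)
        assert cs.calls == ()

    def test_same_seed_reproduces_identical_calls(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=9)[0]
        a = simulate_calls(truth, default_noise_profiles(), GENOME, seed=9)
        b = simulate_calls(truth, default_noise_profiles(), GENOME, seed=9)
        assert a == b

    def test_streams_keyed_by_label_not_order(self):
        """Dropping one caller leaves the other callers' draws unchanged."""
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=13)[0]
        profiles = default_noise_profiles()
        full = simulate_calls(truth, profiles, GENOME, seed=13)
        partial = simulate_calls(truth, profiles[1:], GENOME, seed=13)
        assert full[1:] == partial

    def test_false_positives_avoid_truth_footprint(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=1), seed=21)[0]
        noisy = CallerNoiseProfile(
            caller="fp_only",
            detection_steps=((math.inf, 0.0),),
            fp_rate_per_mb=1.0,
        )
        (cs,) = simulate_calls(truth, [noisy], GENOME, seed=21)
        assert len(cs.calls) > 0
        truth_iv = [e.interval for e in truth.events]
        for c in cs.calls:
            assert total_bp(
                subtract_intervals([c.interval], subtract_intervals([c.interval], truth_iv))
            ) == 0

    def test_recall_matches_detection_probability(self):
        """Mean per-event recall over the panel sits within 3 binomial SDs
        of the mean detection probability over the truth sizes."""
        spec = TruthSpec()
        truths = simulate_truth(GENOME, spec, seed=17)
        profile = default_noise_profiles()[0]
        n = detected = 0
        expected = 0.0
        for truth in truths:
            (cs,) = simulate_calls(truth, [profile], GENOME, seed=17)
            gain = {d: cs.footprint(d) for d in (Direction.GAIN, Direction.LOSS)}
            for e in truth.events:
                n += 1
                expected += profile.detection_prob(e.interval.length())
                hit = total_bp(
                    subtract_intervals([e.interval], gain[e.direction])
                ) < e.interval.length()
                detected += bool(hit)
        p_bar = expected / n
        sd = math.sqrt(p_bar * (1 - p_bar) / n)
        assert abs(detected / n - p_bar) <= 3 * sd

    def test_copy_number_errors_never_flip_direction(self):
        truth = simulate_truth(GENOME, TruthSpec(n_samples=2), seed=23)[0]
        flippy = CallerNoiseProfile(
            caller="flippy",
            detection_steps=((math.inf, 1.0),),
            breakpoint_jitter_sd_bp=0.0,
            fp_rate_per_mb=0.0,
            cn_error_prob=1.0,
        )
        (cs,) = simulate_calls(truth, [flippy], GENOME, seed=23)
        truth_dir = {
            (e.interval.chrom, e.interval.start): e.direction for e in truth.events
        }
        for c in cs.calls:
            assert c.direction == truth_dir[(c.interval.chrom, c.interval.start)]


class TestSimulatedAnnotationInputs:
    def test_genes_deterministic_and_disjoint(self):
        a = simulate_genes(GENOME, n_genes=100, seed=2)
        b = simulate_genes(GENOME, n_genes=100, seed=2)
        assert a == b
        by_chrom = {}
        for g in a:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for x, y in zip(ivs, ivs[1:]):
                assert x.end <= y.start

    def test_terms_draw_from_the_gene_catalog(self):
        genes = simulate_genes(GENOME, n_genes=100, seed=2)
        cat = simulate_terms(genes, n_terms=10, seed=2)
        ids = {g.gene_id for g in genes}
        assert len(cat.terms) == 10
        for _, members in cat.terms.values():
            assert members <= ids and members
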