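# Methods

This note documents the models, conventions and numerical choices behind
`cnvconsensus`, and what the simulator does and does not emulate.

## Coordinates, directions, normalization

All intervals are 0-based half-open internally. Dialects declared as
1-based inclusive are converted on read (`start − 1`; the end coordinate
coincides in the two conventions), so a row `chr1 1 100` covers the same
100 bases either way. The ploidy baseline is fixed at 2 (autosomal
diploid): copy number > 2 is a gain, < 2 a loss, and CN = 2 rows are
skipped with a warning because they carry no variation under this model.
Sex-chromosome ploidy, fractional/sub-clonal copy numbers and
B-allele-frequency evidence are out of scope.

Per caller, overlapping or bookended calls of one direction are merged
into a single call keeping the extreme copy number (maximum for gains,
minimum for losses): when a caller emits fragmented pieces of one event,
the strongest amplitude is the most informative single summary.
Overlapping gain/loss calls from the *same* caller are rejected as
malformed input, with the loci named — they indicate an upstream
processing error rather than a resolvable ambiguity.

## Consensus segmentation

For each direction independently, the union of all callers' intervals is
partitioned at every distinct breakpoint; each atomic piece carries the
exact set of callers covering it plus their copy numbers, and maximal
runs with identical label and copy-number map are re-merged. Because
normalization guarantees per-caller, per-direction disjointness, a
support-constant run always has a constant copy-number map, so the result
is exactly "label every base with its covering-caller set and
recompress" — the property the test suite checks against a literal
per-base oracle.

Three deliberate choices, all configurable or at least explicit:

* **Direction stratification.** A gain and a loss never co-support a
  segment, even when positionally overlapping; merging opposite dosage
  changes would be biologically incoherent.
* **No copy-number agreement required.** A CN=3 and a CN=8 gain
  co-support a shared segment; sharing is positional.
* **No minimum reciprocal overlap.** A 1-bp shared sliver is reported;
  `build_consensus(min_segment_bp=...)` can drop short pieces (default
  1, i.e. keep everything). Breakpoints are deduplicated, so zero-length
  pieces cannot arise.

Multiplicity classes are named unique/double/triple/tetrad for 1–4
supporters (and "k-caller" beyond four); `class_regions` merges bookended
exactly-k segments across supporter-set changes, `footprint` does the
same for multiplicity ≥ k. Venn counts (regions and bp per caller
subset and direction) are tallied from the maximal segments, so per
direction their bp sums to the union of all callers — a conservation law
the tests enforce.

## Gene mapping

A gene joins class k (per direction) when the fraction of its length
covered by the **union** of class-k regions reaches the threshold
(default 0.7). Union coverage, rather than per-single-CNV coverage, makes
the result invariant to arbitrary segment fragmentation: a gene spanning
two adjacent class-k regions separated only by a breakpoint still counts
its full covered length. The threshold comparison is inclusive and
computed with `fractions.Fraction` — "70 % of the gene inside" is read as
attainment, and exact rational arithmetic keeps the boundary case
(700/1000 vs 0.7) independent of floating-point representation. The
assignment records the union of supporting callers over the overlapping
class segments.

## Enrichment

One-sided (enrichment/greater) Fisher exact test per term: the p-value
is the upper hypergeometric tail, evaluated via `scipy.stats.hypergeom.sf`;
the test suite verifies agreement with an exact-rational tail enumeration
to 1e-12 on random tables up to N = 200. The background universe
defaults to all genes in the gene BED (the set of genes that *could*
have been hit); callers may pass any other universe — term genes and CNV
genes are intersected with it before the table is formed, and terms with
no universe genes are skipped with a warning. Raw p-values are always
reported; Benjamini–Hochberg adjustment is applied within each catalog
as standard practice and labelled as such. Depletion testing and
EASE-style corrections are non-goals.

## Evaluation

Scoring is base-level and direction-aware. Every assayed base
contributes two direction slots (GAIN and LOSS); a slot is TP when call
and truth agree there, FP for call-only, FN for truth-only, TN
otherwise. Consequences: TP+FP+FN+TN = 2 × assay bp always; a base
where the call says gain but the truth says loss is charged as both an
FP and an FN — the call is wrong *and* the truth is missed. Copy-number
magnitude is ignored (direction only), and undefined ratios (no calls,
or no truth) are reported as NA, never 0, to avoid fake-perfect scores.
Base-level scoring was chosen over event-level because it is free of
overlap-fraction thresholds and composes additively across samples
(micro-averaging via `sum_counts`).

`evaluate_thresholds` emits one row per caller and one per consensus
threshold k = 1..N, where the k-row scores the merged footprint of all
segments with multiplicity ≥ k. Footprints are nested in k, so TP and
FP are non-increasing in k — the mechanism behind the integration
trade-off.

## Simulator

The simulator models **caller outputs**, not sequencing reads: real
benchmarks of this design run actual detection tools on simulated
sequencing data, which requires those external tools; here the callers
themselves are replaced by parametric noise profiles so the integration
machinery can be exercised end to end. Passing tests therefore
demonstrate the correctness of the consensus/annotation/evaluation
stages and the *qualitative* single-vs-integrated behavior — they say
nothing about any real caller's error model, capture bias, or the
read-level detectability of CNVs in real exomes.

**Truth panels** default to 13 samples × 10 CNVs, sizes uniform in
[500 kb, 4.5 Mb], copy numbers uniform over {1, 3, 4, ..., 20},
non-overlapping with ≥ 1 Mb pairwise gaps, on a 3 × 60 Mb genome (large
enough that placement never strains, small enough to keep interval
algebra instant). Placement is rejection sampling with bounded retries;
infeasible designs raise with a suggestion to enlarge the genome.

**Caller noise profiles** have four ingredients, each with units:

| parameter | meaning | defaults (4 profiles) |
|---|---|---|
| `detection_steps` | piecewise-constant P(detect) vs event size | see below |
| `breakpoint_jitter_sd_bp` | Gaussian SD added to each breakpoint | 10–20 kb |
| `fp_rate_per_mb` | Poisson rate of false events per Mb | 0.02–0.06 |
| `fp_size_range_bp` | log-uniform false-event sizes | 50–500 kb |
| `cn_error_prob` | chance of a ±1 copy-number slip | 0.1 |

The four defaults encode the qualitative size biases reported for the
commonly integrated WES CNV tools — one large-event specialist
(detection 0.50/0.75/0.95 over the <1.5 Mb / 1.5–3 Mb / >3 Mb tiers),
one medium-event specialist (0.65/0.90/0.70), and two small-event
specialists (0.90/0.70/0.55 and 0.85/0.65/0.50), with the small-event
profiles carrying the higher false-positive rates. The numeric values
are this package's choices, picked once to realize those orderings at
realistic WES-like magnitudes. Copy-number slips never cross the
gain/loss boundary (clamped at 3 for gains, 1 for losses), so truth
direction stays well-defined for scoring. False events avoid the truth
footprint so "false" is unambiguous at the base level. Jitter is
truncated to keep calls positive-length and on-chromosome.

All randomness flows from one seed through SHA-256-hashed stable labels
(`truth/<sample>`, `calls/<sample>/<caller>`, `genes`, ...), not
generation order — adding or removing a caller or sample never perturbs
any other stream, and every artifact is a pure function of (spec, seed).

**Benchmark study** (`benchmark.benchmark_scenario/study`): one scenario
simulates a full panel, pools confusion counts over its samples per
caller and per threshold, and the study repeats that over seeds. The
default study size used by `scripts/acceptance.py` — 20 seeds × 13
samples — gives stable medians in seconds; under the default profiles
the median pooled FDR at min_callers = 2 sits roughly an order of
magnitude below the best single caller's, and tetrad precision is at or
above every single caller's in essentially every seed.

## Pipeline and outputs

The `run` subcommand executes read → consensus → min-caller filter →
gene mapping → per-catalog enrichment → evaluation (when truth and
genome files are configured) → TSV writing → HTML rendering. All tables
are sorted under a natural chromosome order (chr1 < chr2 < … < chr10 <
chrX < chrY) with fixed float formatting (`%.6g`), so identical inputs
yield byte-identical outputs. The HTML report is rendered from the same
in-memory objects as the TSVs, embeds no external resources and no
timestamps. The `threads` setting is accepted and validated but stages
run serially: at these problem sizes the pipeline is I/O-trivial, and
serial execution satisfies the contract that outputs match a serial run
for every thread count by construction. Per-chromosome gain/loss plots
are deliberately not embedded; a log notice says so, and the tables
remain the single source of truth (this also keeps the report
byte-stable).

## Known limitations

* The four caller dialect presets are plain chrom/start/end/CN layouts
  under this package's conventions, not transcriptions of those tools'
  native file formats; users integrating real outputs should verify or
  edit the dialect.
* Whether real integration pipelines demand direction agreement,
  copy-number agreement or reciprocal overlap when intersecting callers
  varies by tool; the choices here (direction-stratified, positional
  only, no minimum overlap) are explicit and configurable where
  sensible, but they are conventions.
* The simulator's noise model is output-level; conclusions about real
  WES data require real callers.
* Event-level metrics (per-CNV recall at an overlap threshold) are not
  provided; scoring is base-level only.
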