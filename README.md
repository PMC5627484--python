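# cnvconsensus

Multi-caller consensus, annotation and benchmarking of whole-exome CNV
call sets.

## The problem

Copy-number variations (CNVs) are the dominant structural variants in
cancer genomes, and calling them from whole-exome sequencing (WES) is
attractive — but unreliable: exons are unevenly distributed, so every
single detection tool suffers a high false-call burden and each tool has
its own biases (some favor large events, some medium, some small).
Integrating several callers and keeping only regions supported by
multiple tools is the standard remedy, and trading a little sensitivity
for a large drop in false-discovery rate is usually the right bargain in
clinical settings.

`cnvconsensus` is a caller-agnostic implementation of that integration
step for anyone who already has per-caller CNV segment files. It

1. reads each caller's segments through a configurable **seg-dialect**
   contract (column roles + coordinate convention), so any tool's output
   can be plugged in;
2. partitions the genome at every call breakpoint and labels each piece
   with its exact set of supporting callers — the **caller multiplicity**
   classes *unique* (1), *double* (2), *triple* (3) and *tetrad* (4);
3. maps genes into the class regions by a **coverage fraction** rule
   (default: ≥ 70 % of the gene inside the region set);
4. tests term enrichment of the mapped genes with the one-sided
   **Fisher exact test** plus Benjamini–Hochberg adjustment;
5. benchmarks any call set — single caller or consensus at any
   min-caller threshold — against a truth profile with base-level
   **TPR / FDR / precision**;
6. ships a seeded **simulator** that generates truth panels, noisy
   caller outputs, gene models and term catalogs, so the whole pipeline
   runs and is testable without any external data.

## Model and definitions

All coordinates are 0-based half-open (BED convention); 1-based
inclusive dialects are converted on read. Copy number is scored against
a diploid baseline of 2: CN > 2 is a *gain*, CN < 2 a *loss*, CN = 2 is
dropped with a warning. Gains and losses are stratified everywhere — an
overlapping gain and loss never co-support a segment.

**Consensus.** For each direction, the union of all callers' intervals
is cut at every distinct breakpoint; each atomic piece carries the set
of callers covering it and their copy numbers, and maximal runs with
identical labels are re-merged. For callers *A, B* with gains
[100, 300) and [200, 400), the consensus is [100, 200){A},
[200, 300){A, B}, [300, 400){B}.

**Gene mapping.** Gene *g* is assigned to class *k* (per direction) when

    coverage(g, k) = |g ∩ regions_k| / |g| ≥ τ        (default τ = 0.7, inclusive)

with `regions_k` the merged union of all exactly-*k* segments, so a gene
split across adjacent class regions still qualifies. The comparison is
done in exact rational arithmetic — 700/1000 passes τ = 0.7.

**Enrichment.** For each term the 2×2 table (a = CNV genes in term,
b = CNV genes outside, c = background-only in term, d = rest of
universe) gives the upper hypergeometric tail
P(X ≥ a), X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b); BH adjustment
is applied within each catalog.

**Evaluation.** Scoring is per (base × direction-slot): each assayed
base has a GAIN slot and a LOSS slot, so TP + FP + FN + TN = 2 × assay
bp, a direction-conflicting base counts as both FP and FN, and
TPR = TP/(TP+FN), FDR = FP/(TP+FP), precision = 1 − FDR (reported as NA
when undefined, never 0).

## Worked example

Simulate one sample with the four default synthetic caller profiles and
run the full pipeline on it:

```sh
cnvconsensus simulate --out demo --seed 42 --samples 1 --n-genes 120 --n-terms 12
cnvconsensus run --config demo/S01.cfg
```

`demo/S01.results/` then contains `per_caller_calls.tsv`,
`consensus.tsv`, `genes.tsv`, `enrichment.tsv`, `venn_counts.tsv`,
`metrics.tsv` and a self-contained `report.html`. The consensus table
starts:

```
chrom   start    end      direction  multiplicity  class   callers        per_caller_cn
chr1    409744   525152   loss       1             unique  exomecnv_like  exomecnv_like=0
chr1    1537244  1809700  loss       1             unique  exomecnv_like  exomecnv_like=0
chr1    5867894  5883311  gain       1             unique  excavator_like excavator_like=10
```

and the benchmark columns of `metrics.tsv` (this run) are:

```
call_set        tpr       fdr         precision
adtex_like      0.650807  0.0343752   0.965625
excavator_like  0.832703  0.0198541   0.980146
exomecnv_like   0.242724  0.325184    0.674816
freec_like      0.747116  0.0911048   0.908895
consensus>=1    0.999248  0.186138    0.813862
consensus>=2    0.94268   0.00345686  0.996543
consensus>=3    0.465688  0.000176109 0.999824
consensus>=4    0.0657331 0           1
```

Read it as the integration trade-off: pooling everything (`consensus>=1`)
maximizes sensitivity but inherits every caller's false calls
(FDR 18.6 %); requiring two supporting callers keeps TPR at 94 % while
cutting FDR to 0.35 % — an order of magnitude below the best single
caller (2.0 %); requiring all four drives FDR to zero at a heavy
sensitivity cost. `genes.tsv` lists the genes covered ≥ 70 % by each
class's regions, e.g. `G0021  1  gain  1  freec_like`, and
`enrichment.tsv` holds one Fisher row per term, e.g.
`simGO:0005  a=5 b=7 c=30 d=78  OR=1.86  p=0.245  p_BH=0.978` (nothing
is enriched in a random catalog, as it should be).

Single stages are available as `cnvconsensus evaluate` (metrics from seg
files) and `cnvconsensus enrich` (Fisher test for a gene list), and as
library functions (`build_consensus`, `map_genes`, `fisher_enrichment`,
`confusion_counts`, ...).

## Config file

Flat, case-insensitive `key = value` lines; `caller` and `term_catalog`
repeat. The key names are this package's own (documented here, created
by `simulate` automatically):

```
caller        = name,path[,dialect]   # one line per caller; dialect default "seg"
output_dir    = out                   # required
sample        = S01
gene_bed      = genes.bed             # BED4+: chrom, start, end, gene id
term_catalog  = terms.gmt             # GMT; repeatable
truth         = truth.seg             # optional; enables metrics.tsv
genome        = genome.tsv            # chrom<TAB>length; required with truth
gene_coverage = 0.7
min_callers   = 1
threads       = 1
seed          = 0
```

Dialect presets: `seg` (internal, 0-based half-open, header), `bed5`
(CN in column 5), and `freec` / `adtex` / `excavator` / `exomecnv`
(1-based inclusive presets intended as editable starting points — see
`cnvconsensus.io.DIALECTS`).
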