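# Methods

## Quantities and estimators

All rate and level estimators are read-weighted pooled ratios: for a
selection of per-cytosine calls, the estimate is Σ protected / Σ total, the
maximum-likelihood estimate of a common per-read probability. Site-averaged
means (the unweighted mean of per-site ratios) weight shallow sites as much
as deep ones and are biased at low coverage; a site-level variant of the
global estimator exists behind `global_5hmCG(..., site_level=True)` for
sensitivity analysis only.

Calibration uses three selections: CG calls of the fully-5mC lambda spike-in
(5mC non-conversion), CHG/CHH calls of the genomic sample (unmodified-C
non-conversion), and CG calls of the fully-5hmC pUC19 spike-in (protection
rate π). The global raw %5hmCG is 100 × the pooled CG ratio of the genomic
sample; the scaled value divides by π and is capped at 100% with a warning.
No background subtraction of non-conversion is applied to %5hmCG: the
non-conversion rates are reported as QC alongside the raw and scaled values.
Protection rates are estimated and applied per sample, never pooled across
samples. Internal arithmetic is full precision; display values round
half-even to two decimals.

Genome-equivalents coverage is estimated as Σ total read observations over
all calls divided by the number of cytosine sites in the reference — mean
depth per reference cytosine. This is a proxy; any definition proportional
to read yield gives the same subsampling behaviour.

## Coordinates and binning

Internal coordinates are 0-based half-open everywhere; BED12 is native and
GFF3 is converted on read (start decremented). Duplicate (chrom, pos,
strand) call records are an error, never merged, and CG records are kept
per strand (pooling handles both strands; merging strands upstream would
silently halve site counts).

Each gene defines 60 intervals in transcription orientation. Body bin k of a
gene spanning [start, end), length L, covers
[start + ⌊kL/20⌋, start + ⌊(k+1)L/20⌋) on the plus strand and its mirror on
the minus strand; this partitions the body exactly for any L ≥ 20, with bin
widths differing by at most 1. Genes shorter than the bin count are skipped
(logged). Flank bins have fixed width (default 5 kb × 20 = 100 kb per side);
bins running off a contig are clipped and flagged rather than dropped. Flank
bins overlapping neighbouring genes are not masked. Bin 0 of the upstream
region is the farthest from the TSS, so minus-strand genes reverse genomic
order; a mirror-symmetry test (reverse-complementing coordinates and
strands) verifies orientation handling exactly.

Quintile profiles pool counts across member genes before dividing
(read-weighted across genes, consistent with the weighted-level definition);
a gene-averaged variant (`gene_averaged=True`) averages per-gene bin levels
instead. A bin with zero pooled coverage is emitted as missing (NaN), never
as level 0. Profiles are raw by default; `protection_rate=` divides all
levels for protection-scaled profiles. The Q5/Q1 gene-body fold change pools
the 20 GB bins' counts within each profile before forming the ratio, so it
is invariant to protection scaling.

## Expression quintiles

The score is mean expression across samples divided by total exonic length.
Genes are sorted ascending by (score, gene_id) — lexicographic gene-id
tie-break makes the partition order-invariant — and split into five lists:
base size ⌊n/5⌋ with the n mod 5 extra genes given to the lowest quintiles
(for n = 25,321: 5,065 + 4 × 5,064). Zero-expression genes are retained in
quintile 1; no expression filter is applied.

## Statistics

The two-sample comparison is Pearson's chi-square (df = 1) on
[[protected, converted], [protected, converted]] without continuity
correction — counts are ~10⁵, where the correction is immaterial — computed
with scipy and cross-checked in the tests against the closed form
Σ(O−E)²/E and the algebraic identity with the squared two-proportion
z-statistic. Raw counts are used (scaling a count table by a protection rate
is not well defined); raw p-values are reported and multiple-testing
correction is left to the caller.

## Synthetic data generator

The generator emulates shallow TAB-seq of sorted nuclei over a toy genome:
i.i.d. random sequence at GC content 0.42 (2 × 500 kb by default), 200
non-overlapping genes with 1–3 exon blocks placed one per equal-width slot,
a 16-sample expression table, and site-level reads
``total ~ Poisson(coverage)``, ``protected ~ Binomial(total, p)``. Per-read
probabilities p: quintile-specific values at gene-body CG sites (defaults
0.010, 0.017, 0.024, 0.031, 0.038 for quintiles 1–5, a 3.8-fold Q5/Q1
contrast), a background of 0.020 at other CG sites (so the lowest quintiles
sit *below* flank level, the qualitative gene-body pattern of interest),
non-conversion 0.005 at genomic non-CG sites, 0.03 at lambda CG sites
(fully 5mC), and protection 0.52 at every pUC19 cytosine (PCR with 5hmdCTP
hydroxymethylates all of them). The gene-body and background values are
*net* per-read protected probabilities — the level the assay measures — so
configured contrasts propagate directly to the raw weighted levels;
``unmethylated_cg_fraction`` optionally reassigns a fraction of background
CG sites to the unmodified-C non-conversion rate. Spike-ins are sequenced at
30× so each rate estimator rests on ≥10⁴ read observations.

Expression truth: each gene draws a base score in a quintile-specific band a
decade apart, multiplied by exonic length, a per-sample scale factor and
log-normal noise (σ = 0.2); averaging 16 samples cannot move a gene across
bands, so the pipeline's quintile assignment reproduces the configured
labels exactly, which the tests assert. Everything is deterministic given
the config seed (one `numpy` Generator, fixed draw order).

What the generator does **not** emulate: real genome composition (CpG
islands, repeats), fragment/read geometry, mapping and trimming artefacts,
PCR duplicates, and sequencing-error substitutions beyond conversion
chemistry. Passing tests therefore validate the estimators, the binning
arithmetic and their statistical calibration — not robustness to alignment
or composition artefacts in real data.

## Problem sizes and numerical choices

Default toy chromosomes (2 × 500 kb) cannot hold 100 kb flanks for 200
genes, so the generator defaults to 100 bp flank bins (2 kb flanks); the
flank width is a parameter that flows through the bin scheme, and the
100 kb/5 kb full-scale geometry is verified directly on single genes. The
subsampling robustness check uses a larger genome (2 × 3 Mb, 300 genes) at
13× thinned to 0.2×, sized so the adjacent-quintile gene-body gaps are
≈3.3 standard errors at 0.2× and the configured ordering is statistically
resolvable. Calibration recovery is checked over 100 seeded replicates
against exact Clopper–Pearson 99% intervals, requiring ≥99/100 coverage per
estimator; profile-agreement checks over ~300 simultaneous 3-SD bands
require ≥99% of bins inside, the family-level rendering of a per-bin 3-SD
check (expected exceedance ≈0.3%).

Subsampling thins each site's protected and converted read counts as
independent binomials — the exact law of retaining each read independently —
and drops emptied sites; fractions above 1 are rejected (no upsampling).

## Known limitations

* The fold-change estimator is a ratio of pooled small counts; at 1×
  coverage on the default toy genome its sampling SD is ≈13% per dataset
  and ratio convexity inflates its mean by ~2–4% above the configured
  contrast. Averaging ten seeds leaves ≈4% SE on the mean.
* The coverage metric is a proxy (mean depth per reference cytosine), not a
  mappability-aware genome-equivalents calculation.
* TAB-seq cannot separate C from 5mC; nothing here estimates 5mC, and
  per-site statistical 5hmC calling is out of scope (aggregate levels only).
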