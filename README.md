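# hydroxymeta

Spike-in–calibrated quantification of 5-hydroxymethylcytosine (5hmC) from
TAB-seq data: global %5hmCG with protection-rate scaling, expression-quintile
stratification of genes, strand-aware metagene profiles of weighted 5hmCG
levels, coverage subsampling, and a synthetic-data generator with known truth
for every estimator.

## The problem

TET-assisted bisulfite sequencing (TAB-seq) reads out 5hmC specifically:
beta-glucosyltransferase protects 5hmC, TET oxidises 5mC, and bisulfite
converts everything unprotected, so only 5hmC is reported as C. The assay is
imperfect in both directions, and two spike-in controls calibrate it per
sample:

* a fully CG-methylated lambda phage DNA measures the **5mC non-conversion
  rate** (false positives from 5mC); genomic CHG/CHH cytosines measure the
  non-conversion of unmodified C;
* a fully hydroxymethylated pUC19 plasmid measures the **protection rate**
  π — the fraction of true 5hmC the assay recovers.

With pooled read counts over CG-context cytosines, the global level is the
weighted methylation level

```
%5hmCG = 100 · Σ protected / Σ total        %5hmCG_scaled = %5hmCG / π
```

pooled over reads, never averaged over sites. Because shallow whole-genome
coverage (fractions of a genome equivalent) cannot support per-site calls,
gene-level structure is read out as **metagene profiles**: each gene
contributes 60 bins in its own 5'→3' orientation — 20 fixed-width bins
upstream of the TSS (5 kb each, 100 kb total, at full scale), 20 bins evenly
partitioning the gene body whatever its length, 20 downstream of the TTS —
and counts are pooled across all genes of an expression quintile before
dividing. Genes are ranked into quintiles by mean RNA-seq expression divided
by total exonic length (quintile 1 = lowest). Two samples' global levels are
compared with an uncorrected Pearson chi-square on the 2×2 table of
protected vs converted read counts, and the gene-body contrast between
extreme quintiles is summarised as the pooled-level fold change Q5/Q1.

## Worked example

```python
import hydroxymeta as hm
from hydroxymeta.pipeline import calibration_summary, quintile_metagene
from hydroxymeta.stats import gene_body_fold_change

ds = hm.simulate_dataset(hm.SimulationConfig(seed=42))   # 2 x 500 kb, 200 genes, 1x
print(calibration_summary(ds)[["nonconv_5mC", "nonconv_C", "protection_rate",
                               "pct_5hmCG", "scaled_pct_5hmCG", "coverage"]].round(4))

assignment, profiles = quintile_metagene(ds)
for q in (1, 5):
    print(f"Q{q}: gene body {profiles[q].region_level('GB'):.4f}, "
          f"upstream {profiles[q].region_level('UTSS'):.4f}")
print("fold(Q5/Q1) =", round(gene_body_fold_change(profiles[5], profiles[1]), 2))
```

prints

```
   nonconv_5mC  nonconv_C  protection_rate  pct_5hmCG  scaled_pct_5hmCG  coverage
        0.0296     0.0051           0.5129     2.2296            4.3471    0.9983
Q1: gene body 0.0102, upstream 0.0212
Q5: gene body 0.0392, upstream 0.0199
fold(Q5/Q1) = 3.84
```

The spike-in estimators recover the generator's truth (0.03 / 0.005 / 0.52)
from the simulated read counts; the quintile-5 gene body is enriched above
its flanks while quintile 1 drops below them; and the configured 3.8-fold
gene-body contrast between the extreme quintiles is recovered by the full
pipeline (here 3.84). The same stages are exposed as a CLI
(`hydroxymeta simulate | calibrate | global | quintiles | metagene |
subsample | compare`), each writing TSV outputs plus a reproducibility
manifest.

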