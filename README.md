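# embryomark

Integrated analysis of histone-mark ChIP-seq and transcription across
embryonic tissues: binary mark calling on 1 kb genome bins, promoter
chromatin-state classification, cross-tissue regulatory pattern analysis,
tissue-specific enhancer discovery, enhancer-to-gene correlation over
megabase windows, and de novo mutation (DNM) enrichment testing.

## The problem

During organogenesis the same genome drives alternative organ fates by
selectively activating and repressing regulatory elements. Mapping that
landscape across many tissues at once requires comparing ChIP-seq signal
for H3K4me3 (active promoters), H3K27ac (active enhancers/promoters) and
H3K27me3 (Polycomb repression) between tissues and replicates on a common
footing, and tying the resulting elements to the genes they control. This
package implements that comparative machinery as a tested library, and — 
because the primary human-embryo datasets are access-controlled — ships a
synthetic-data generator that plants known tissue patterns, promoter
states, enhancer–target couplings and mutation-rate enrichments, so every
stage can be exercised end to end against ground truth.

## The core procedures

* **Elbow mark calling.** The genome is cut into non-overlapping 1 kb bins
  and read starts counted per bin. Ranking a sample's counts ascending
  gives a hockey-stick curve; with rank and count min–max normalised, the
  *elbow* is the point nearest (Euclidean) the corner (max rank, 0). A bin
  is *marked* iff its count strictly exceeds the elbow count. Replicate
  agreement is the phi coefficient of the binary call vectors. Before
  calling, bins saturated in all samples (>10,000 reads), dominated by
  input control (input mean ≥ 50% of ChIP mean), or pericentromeric are
  removed, and counts are equalised across samples by binomial thinning to
  the smallest per-sample 99th-percentile nonzero count.
* **Promoter states.** Per gene, signal for the three marks plus RNA is
  profiled over TSS ± 3 kb in 100 strand-oriented windows; genes are
  k-means clustered (k = 5 by default) on within-gene rank profiles, and
  each cluster is classified by threshold rules into one of seven states:
  actively repressed (H3K27me3 > 50% of max, RNA < 10%), narrow expressed
  (H3K4me3 > 25% of max, > 90% of reads downstream, skew > 0.65,
  RNA > 10%), broad expressed (as narrow, skew < 0.65), bidirectional
  expressed (< 90% downstream), bidir2, expressed2, and inactive. Skew is
  the weighted moment skewness of the window index over TSS→+3 kb.
  Cross-tissue tables amalgamate transcribed states and report per tissue
  the *disallowed* genes: expressed uniquely there and H3K27me3-repressed
  in every other tissue. A Fisher exact test asks whether transcription
  factors are over-represented among genes repressed somewhere.
* **Patterns.** A bin's pattern is the exact subset of samples in which it
  is marked; patterns are frequency-ranked (requiring ≥ 2 samples), and
  tissue-specific / tissue-selective / shared bin sets derived.
* **Enhancer discovery.** Peaks with RPKM ≥ 25 and ≥ 2.5-fold over every
  reference-compendium sample are kept; tissue specificity is then imposed
  by a sequential random-order overlay in which any peak covered ≥ 50% of
  its length by the other datasets is dropped and residual overlapping
  bases are subtracted, with a final > 200 bp filter. Concordance between
  two dataset orders is measured base-level.
* **Target correlation.** Downsampled counts are averaged within tissues
  and Pearson-correlated, across tissues, with expression of every gene
  whose TSS lies within 1 Mb of the bin midpoint.
* **DNM enrichment.** Surveyed non-coding regions (UCE/EVE/PHE) and their
  DNMs are overlaid on the calls (± 1 kb); enrichment is observed/expected
  under a uniform-per-base null with an exact Garwood (chi-square) Poisson
  95% CI.

## Worked example

```python
from embryomark import (SimConfig, simulate_dataset, filter_bins,
                        downsample_counts, call_marks, pattern_table)

cfg = SimConfig(seed=1)                      # 6 tissues x 2 reps, 10,000 bins
counts, genes, expression, truth = simulate_dataset(cfg)
calls = call_marks(downsample_counts(counts, seed=2), filter_bins(counts))
k27 = calls.subset_samples(lambda s: s.mark == "H3K27ac" and not s.is_input)
print(pattern_table(k27, min_samples=2).head(3))
```

prints

```
                                  pattern  n_bins  rank
0    (liver_H3K27ac_r1, liver_H3K27ac_r2)     284     1
1    (brain_H3K27ac_r1, brain_H3K27ac_r2)     283     2
2  (palate_H3K27ac_r1, palate_H3K27ac_r2)     277     3
```

i.e. the most frequent cross-sample patterns are the planted
tissue-specific ones (~300 bins were planted per tissue; the elbow calls
recover them with sensitivity 1.00 and a ~1% false-mark rate on this
dataset).

The numbered scripts under `analysis/` run each stage of the full study on
synthetic data and write their tables under `results/`:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_mark_calling.py
...
python analysis/07_dnm_enrichment.py
```

For instance, `analysis/07_dnm_enrichment.py` plants a 1.45× per-base DNM
rate ratio inside marked elements and reports
`DNM enrichment in H3K27ac elements: 1.33 (95% CI 1.08-1.62)`, and
`analysis/03_promoter_states.py` reports ≥ 99% recovery of planted
promoter states and the TF-repression odds ratio 1.82 recomputed from the
published marginal counts.

## Command line

A thin CLI (`embryomark simulate | bin-counts | filter-bins | downsample |
call-marks | patterns | run | enhancers-concordance`) wraps the library
for shell use; `embryomark run --out dir/ --seed 1` executes the full
pipeline with a reproducible manifest.
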