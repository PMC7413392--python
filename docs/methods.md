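# Methods

This note documents the models, rules and numerical choices behind
`embryomark`, what the synthetic data does and does not emulate, and the
problem sizes the analyses run at.

## Genome binning, filtering and downsampling

The genome is partitioned per chromosome into contiguous, non-overlapping
bins of `bin_width` (default 1,000 bp), 0-based half-open; the final bin of
a chromosome is truncated rather than dropped, so every base is covered
exactly once. Reads are counted by mapped start position; strand is
ignored.

Three bin filters run in a fixed order (each removed bin records the first
matching reason, for reproducible reporting):

1. *saturated* — count > 10,000 in **every** non-input sample;
2. *input_dominated* — mean count over input controls ≥ 50% of the mean
   over non-input samples, evaluated per bin;
3. *pericentromeric* — ≥ 1 bp overlap with a supplied interval list.

When no input samples are present the second rule is skipped with a
warning rather than an error.

Downsampling equalises signal scale across samples by binomial thinning:
for each sample the 99th percentile of its **nonzero** bin counts is the
scale `q_s` (zeros dominate genome bins and would nullify a raw quantile);
each count is thinned with retention probability `min(1, t/q_s)` where `t`
is the smallest `q_s` in the comparison group. The comparison group is the
samples of one histone mark (`per_mark=True`, the default): comparisons are
always within a mark, and a global minimum would let an input track or a
low-signal mark destroy another mark's counts. A global-minimum mode is
available (`per_mark=False`).

## Elbow mark calling

Counts are sorted ascending (ties broken by position, so the ranking is
stable), rank mapped to `x = r/N` and count to `y = c_r / max(c)`. The
elbow is the rank minimising `(1 - x)^2 + y^2` — the point nearest the
corner (max rank, zero count) — with ties resolved to the smallest rank. A
bin is marked iff its count is **strictly** greater than the count at the
elbow. A constant count vector has no elbow; the call returns that value
as threshold, marks nothing and warns. The implementation is asserted
equal, rank for rank, to an exhaustive minimisation oracle on 1,000 random
vectors.

Two geometric facts worth knowing: the threshold is invariant under
multiplying all counts by a positive constant (both axes are min–max
scaled), and a single extreme outlier raises `max(c)`, flattens `y`, and
pushes the elbow right — one reason the saturation filter precedes
calling. Elbow thresholds are computed on downsampled counts, after bin
filtering; masked bins are never marked.

Replicate agreement uses the phi coefficient,
`(n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)`, which equals the
Pearson correlation of the 0/1 vectors; it is NaN when any margin is zero.

## Promoter states

Profiles cover TSS ± 3 kb in 100 windows of 60 bp, strand-oriented so the
last window is always +3 kb in the transcribed direction; the downstream
half therefore has 100 equidistant points after linear resampling, which
is the grid on which skew is measured. Skew is the moment coefficient of
skewness g1 = m3/m2^1.5 of the window index weighted by counts — the named
statistic with the standard formula, since only the name and cut-off
(0.65) are fixed by the procedure. It is antisymmetric under profile
reversal and undefined (NaN) for empty or constant-support profiles.

Clustering is k-means (25 restarts, fixed seed) on the within-gene rank
transform of each track's profile, tracks concatenated. Replicates are
averaged **in rank space**: the feature matrix is the mean of the
per-replicate rank transforms. Averaging raw counts first turns out to be
subtly destructive — it halves the tie mass of low-signal profiles, so the
ranks of inactive/repressed genes scatter and k-means spends clusters
splitting noise while merging narrow with broad expressed; rank-then-
average preserves the tie structure and recovers planted partitions
exactly. Cluster mean *signal* (used by the classifier) still comes from
count-averaged profiles. Each replicate is also clustered and classified
alone, giving a per-gene concordance flag; concordance is reported, not
enforced.

Classification applies threshold rules to cluster-mean signal relative to
the maximum cluster-mean for that track within the tissue ("maximum" is
cluster-level because classification is applied to clusters). Rules run
in a fixed order, first match wins:

| state | rule |
|---|---|
| actively_repressed | H3K27me3 > 50% of max and RNA < 10% of max |
| narrow_expressed | H3K4me3 > 25% of max, downstream fraction > 0.90, skew > 0.65, RNA > 10% |
| broad_expressed | as narrow but skew < 0.65 |
| bidirectional_expressed | H3K4me3 > 25%, downstream fraction < 0.90, RNA > 10% |
| bidir2 | H3K4me3 ≤ 25% and RNA > 10% |
| expressed2 | H3K4me3 > 25% and RNA < 10% |
| inactive | H3K4me3 and H3K27me3 < 25%, RNA < 10% |

All boundary values are strict inequalities. The bidir2 rule drops the
downstream-fraction clause: "bidirectional without the H3K4me3 signal"
leaves that fraction meaningless when the defining track is absent, so the
state is operationalised as transcribed-without-H3K4me3 and ordered after
bidirectional. A cluster matching no rule falls back to inactive with a
low-confidence flag. Because every rule compares fractions of per-tissue
maxima, classification is invariant to scaling a tissue's signals by any
positive constant. "Mean transcript counts" is the mean of the ± 3 kb RNA
profile (a gene-level count would need annotation lengths that the profile
set does not carry). Expressed2 represents the long-gene detection
artefact as a state only; no gene-length correction is applied.

Cross-tissue analysis amalgamates the transcribed states — narrow, broad,
bidirectional and bidir2 — into one *expressed* category (expressed2 is
excluded: its TSS transcript signal is below threshold by definition, and
rescuing it would require gene-level counts). For each tissue, genes
expressed uniquely there are split by their state elsewhere: repressed in
**all** other tissues (*disallowed*), inactive in all (*inactive
elsewhere*), or a mixture (an explicit residual set rather than a silent
drop). The TF test is a two-sided Fisher exact on TF/non-TF ×
repressed-in-≥1-tissue, odds ratio (a·d)/(b·c).

## Patterns and bin sets

A pattern is the exact sample subset in which a bin is marked; bins marked
in fewer than `min_samples` (default 2) samples are excluded, and the sum
of pattern counts equals the number of surviving bins (a property test
asserts this on random matrices). Ranks are dense, descending by count,
ties broken by the pattern bit-vector. Tissue-specific bins are marked in
every replicate of exactly one tissue and nowhere else; tissue-selective
bins are marked in the tissue's replicates and in at most half of all
samples (the tissue's own replicates count toward the cap); shared bins
are marked in more than half of all samples. Input samples are excluded
throughout; an unreplicated tissue cannot be queried but its samples still
count as "other samples".

## Enhancer overlay

The enrichment filter keeps peaks with RPKM ≥ 25 **and** ≥ 2.5× every
reference sample's RPKM over the same region; an empty reference degrades
to the absolute floor with a warning. The specificity overlay processes
peak sets in a seeded random order. At each addition, overlap is measured
as overlapping bases divided by the peak's **own** length, symmetrically
for incoming and existing peaks; peaks at ≥ 50% are dropped, and residual
overlapping bases are subtracted from the survivors (subtraction, not
whole-peak removal — survivors by definition overlap < 50%). Incoming
peaks are judged and trimmed against the cumulative raw footprint of every
dataset added so far, not merely the current survivors: otherwise a peak
present in three datasets would resurface as "specific" in the third after
the first two copies annihilate each other, and the result would depend
strongly on order. With the footprint rule the output is near
order-invariant (base-level concordance between two random orders is
~100% at ≤ 1% inter-tissue overlap) and is verified against a brute-force
per-base replay of the same sequential rule. Fragments ≤ 200 bp are
discarded at the end; outputs are mutually non-overlapping and are always
subsets of input bases.

## Target correlation

Downsampled counts are averaged within tissues (arithmetic mean over
replicate columns of one mark). For each query bin, every gene whose TSS
lies within 1 Mb of the bin midpoint (closed bound; distance anchored at
the midpoint since no anchor is canonical) is Pearson-correlated across
tissues against the bin's signal vector, untransformed by default (a
log1p option exists). Negative r is reported — anticorrelation is
meaningful. At least 3 shared tissues are required; with fewer the
operation refuses rather than returning meaningless r. Constant vectors
yield NaN for that pair.

## DNM enrichment

A region overlaps a mark when the region expanded ± 1 kb (clipped at
chromosome ends) intersects a marked bin by ≥ 1 bp; "replicated" overlap
requires a bin marked in both replicates of some tissue. The enrichment
ratio is observed/expected with expected = total DNMs × (surveyed bases
covered by expanded elements / total surveyed bases) — a uniform-per-base
null within surveyed regions, the minimal assumption; an element-count
null (`null="per_element"`) is also implemented. The 95% CI is the exact
Garwood interval, `lo = χ²(α/2; 2k)/2` (0 for k = 0),
`hi = χ²(1−α/2; 2k+2)/2`, applied to the observed count and divided by
the expected count. The bounds are verified against a definition-based
oracle (solving the Poisson tail equations numerically) and achieve ≥ 95%
empirical coverage. Note the ratio estimand is attenuated toward 1 as the
covered fraction of surveyed bases grows — with covered fraction c and
true rate ratio ρ the point estimate converges to ρ/(ρc + 1 − c) — so
recovery experiments keep marked elements sparse (~10% of surveyed bases).

## Synthetic data: what it emulates, and what it does not

Background bin counts are negative binomial with var = μ + φμ²
(μ = 1 read/bin, φ = 0.3 by default): ChIP bin counts are overdispersed,
and the distribution's zero mass matches the empty-genome regime. Planted
bins add Poisson(30) signal in the samples of their pattern (30× the
background mean). Input tracks carry 0.1× the ChIP background depth —
inputs hold no planted signal, and at equal depth the per-bin
input-domination filter would flag most of the background genome, which is
not the sparse-removal regime the filter is meant for. Enhancer–target
pairs share a per-tissue latent normal z: expression ∝ exp(0.6·z), bin
activity ∝ exp(0.6·(ρz + √(1−ρ²)ε)), so the log-scale correlation is the
configured coupling ρ and the planted bin lies within 1 Mb of its target's
TSS. TSS profile archetypes realise the state definitions (narrow: sharp
exponential decay downstream, skew ≈ 2.3; broad: a plateau of twice the
width and double the RNA, skew ≈ 0.33; bidirectional: symmetric H3K4me3;
repressed: a broad H3K27me3 dome with near-zero RNA; inactive:
background), each gene scaled by a lognormal amplitude (σ = 0.25) with
Poisson counting noise per replicate. DNMs are Poisson-placed per base at
`dnm_rate_marked` inside ± 1 kb-expanded marked elements and
`dnm_rate_unmarked` elsewhere within surveyed regions whose category
composition (UCE 70%, EVE 10%, PHE 20%) mirrors the surveyed compendium.

The generator is deterministic given its seed. It does **not** emulate raw
reads, fragment-length effects, GC or mappability bias, copy-number
artefacts, correlated noise between marks, cellular heterogeneity, or
realistic gene/peak length distributions — so passing tests demonstrate
the correctness and statistical behaviour of the procedures under the
declared noise model, not performance on real embryonic chromatin.

## Study conditions and problem sizes

The toy genome is 2 chromosomes × 5 Mb (10,000 bins): large enough for
± 1 Mb windows, small enough for seconds-scale stages. The default dataset
plants 300 tissue-specific H3K27ac bins per tissue plus 200 shared, and
carries 5,000 genes over 6 tissues × 2 replicates with state mix narrow
0.15 / broad 0.25 / bidirectional 0.10 / repressed 0.15 / inactive 0.35 —
the five major states; the two minor states and the weak-H3K4me3
repressed archetype are exercised by dedicated tests with explicit mixes
and extended k (the bivalency search), where the extra archetype isolates
into its own H3K27me3 sub-cluster at k = 10. The correlation analysis
runs its stated conditions — 12 tissues, coupling 0.9, ~44 genes per 2 Mb
window (220 genes on the toy genome), 40 planted pairs. The DNM analysis
uses sparse marked elements (6 × 50 + 30 shared bins) and rates 8.7e-4 vs
6.0e-4 per bp (the observed 1.45 ratio, scaled so the ~1 Mb surveyed
territory yields several hundred mutations, the count regime of the
original cohort); the default config keeps the same 1.45 ratio at
cohort-level per-base rates. These sizes are fixed in
`embryomark/configs.py` so the analysis drivers, tests and the acceptance
script run identical experiments.

## Known limitations

* The elbow threshold inherits sensitivity to the maximum count; heavy
  right tails shift it upward. The saturation filter mitigates but does
  not remove this.
* Promoter-state accuracy is reported for archetypes the generator itself
  defines; real promoter shape variation is broader.
* The overlay's 50% rule is sharp: peaks near the boundary can flip
  between orders, which is what the concordance metric quantifies.
* The DNM ratio attenuates with element coverage (formula above); ratios
  from dense element sets underestimate the underlying rate ratio.
* No multiple-testing correction is applied to per-phenotype DNM tests or
  to correlation r values; the reported quantities are estimates with
  intervals, matching the source procedures.
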