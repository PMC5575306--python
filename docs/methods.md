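# Methods

## Signal model

MeDIP-seq read depth in a genomic window is, to first order, proportional
to (methylation level) × (local CpG density) × (library depth). The
pipeline therefore works on three per-window quantities: the raw
deduplicated fragment count, the size-factor-normalized count, and — where
a methylation *level* rather than an enrichment signal is needed — the
relative methylation score obtained by dividing the normalized count by the
window's CpG count (the coupling vector). Raw and normalized counts are the
inputs to differential testing; the coupling-corrected score is used when
methylation is compared across loci with different CpG densities, as in the
promoter-methylation/expression correlation, because the uncorrected signal
confounds methylation with CpG density.

Coordinates are 0-based half-open everywhere; BED is native, GTF is
converted on read. N bases never count as C, G or CpG, and all GC
fractions and densities use the N-free (effective) length.

## Windowing, counting, normalization

- Windows: non-overlapping 1 kb tiles per chromosome (`window_bp`,
  default 1000; the final partial window is kept). X/Y chromosomes are
  excluded by default (name-pattern filter, configurable) to avoid
  sex-linked methylation differences.
- Deduplication: within a sample, fragments with identical
  (chrom, start, end) collapse to one representative. Identical coordinates
  in different samples are kept.
- Counting: a fragment increments every window it overlaps by ≥ 1 bp, so a
  boundary-spanning fragment counts in two windows.
- Normalization: median-of-ratios size factors over windows with positive
  counts in every sample; `normalized = raw / size_factor` columnwise.
  Windows with zero counts in all samples are untestable and excluded from
  testing (their t is undefined).

## Differential testing and FDR

For each testable window the paired t statistic is computed on per-subject
differences of normalized counts (sample sd, n−1 denominator). Degenerate
windows with zero sd get t = 0 when the mean difference is also zero and
signed infinity otherwise; infinite-t windows are called (they exceed any
threshold) but are dropped from clustering distances. DMRs are windows with
|t| **strictly** greater than the threshold (default 7); direction is the
sign of the mean treated−control difference.

The threshold is accepted as configuration, not re-derived: it presumes a
deep study (the regime it was calibrated in), and the package additionally
reports t-distribution quantiles through the t vector itself rather than
guessing a derivation rule.

Permutation FDR: within each non-DMR testable window, the 2n values are
independently permuted across all sample slots and the paired t recomputed;
exceedances of the threshold are counted per permutation. This breaks both
the pairing and the group labels, giving a null of no treatment effect
while preserving each window's marginal count distribution — the closest
valid reading of "shuffle the normalized read counts for each non-DMR
window". Because only non-DMR windows are permuted, the mean exceedance is
rescaled by N_testable/N_nonDMR (toggleable) before dividing by the
observed DMR count; the estimate is capped at 1 and is reproducible under a
fixed seed. With zero observed DMRs the FDR is reported as not applicable.

Sample clustering on DMR windows uses 1 − Pearson correlation between
sample columns with average linkage; cutting at two clusters yields the
flat grouping. Constant columns are rejected by name.

## Feature model

- CpG islands: regions > 200 bp with GC ≥ 0.5 and CpG obs/exp > 0.6, where
  obs/exp = (#CpG × L)/(#C × #G) on the effective length. The caller is a
  Takai–Jones-style scan: every 200 bp window (1 bp step) is tested,
  overlapping/adjacent qualifying windows are merged, and the merged span is
  re-tested against all three criteria (a merged span that fails is
  dropped rather than shrunk — deterministic and oracle-checkable).
- Shores: up to 2 kb on each island flank, clipped at chromosome edges and
  truncated at neighbouring islands (union of flanks minus union of
  islands), so islands and shores never double-cover a base.
- Promoters: −2,200..+500 around the TSS, strand-aware, clipped at
  chromosome bounds. CpG classes scan 500 bp windows at 5 bp steps with
  Weber-style thresholds: HCP if any window has obs/exp ≥ 0.75 and
  GC ≥ 0.55; LCP if no window reaches obs/exp ≥ 0.48; else ICP. Promoters
  shorter than 500 bp are scored as a single window.
- Assignment: one label per region by largest bp overlap, ties broken by
  the precedence CGI > promoter > exon > intron; no overlap is intergenic.
  Intergenic regions keep their label; the nearest gene distance is
  available as a separate diagnostic rather than folded into the label.
- Enrichment: ratio_f = (n_f/N) / (bp_f/bp_genome) with
  precedence-resolved disjoint footprints, so the footprints partition the
  genome and uniformly placed regions give ratios of 1 in expectation.

## Profiles and descriptive statistics

Per-base depth is each window's normalized count spread uniformly over its
bases (the underlying data's finer structure is not recoverable from window
counts, so uniform spreading is the neutral choice). Metagene profiles use
20 upstream bins over 2.2 kb (110 bp each), 50 equal fractional gene-body
bins and 20 downstream bins, oriented 5'→3' per gene strand; the profile is
the across-gene mean. CGI profiles use 20 bins per fixed 2 kb flank and 20
fractional island bins; fixed flanks keep bins comparable across islands
even where a shore was truncated. The subtelomere contrast takes the span
(default 7 Mb) at **both** chromosome ends — the orientation of "downstream
of the telomere" is otherwise ambiguous — and applies a pooled-variance
Student t against the interior windows, skipping chromosomes shorter than
twice the span. Saturation analysis splits one sample's fragments into
random halves and reports the Pearson correlation of window counts between
equally subsampled halves per fraction.

## Integration with expression

Expression quartiles rank genes by mean expression after removing silent
genes (undetected in both groups); ties break by gene id so the split is
deterministic. The genome-wide association is the Pearson correlation of
coupling-corrected promoter methylation with log2(expression + 1); it is
computed per group since group methylomes differ. The DM×DE overlap uses a
2×2 chi-square without continuity correction (df = 1) on a universe of
genes with both measurements; when any expected cell is below 1 a warning
is raised and the Fisher exact P reported alongside. The universe
definition materially changes this P, so the test is reported with its
table rather than treated as a portable constant. 2^−ΔΔCt converts qPCR Ct
quadruples to fold changes.

## Synthetic study generator

The generator emulates a paired stimulation study at desk scale. Defaults
(the `default` preset): 2 chromosomes × 1 Mb, 1 kb windows (2,000
windows), 10 CG-rich blocks per Mb, 100 planted DMRs at 2-fold effect with
a 40% hyper / 60% hypo mix, 6 subject pairs, 300 genes, inverse
methylation→expression coupling. Everything is reproducible from one seed
(per-stage child streams).

- **Genome**: background bases i.i.d. at 40% GC with 80% of CpG
  dinucleotides destroyed (obs/exp ≈ 0.2, matching the CpG depletion of
  mammalian bulk genome); planted blocks i.i.d. at 65% GC (obs/exp ≈ 1),
  700–1,500 bp, ≥ 5 kb apart.
- **Methylome**: control methylation per window ~ Beta(2,2); treated equals
  control except planted windows ×2 (hyper) or ÷2 (hypo), clipped to
  [0,1]. CpG density enters the observable through the count model's
  coupling term, not the methylome itself (scaling both would double-count
  density); a `cpg_weight` knob exists for density-shrunk methylomes.
  DMRs are planted only where the effect is realizable and measurable:
  CpG coupling at or above the median of CpG-containing windows, control
  methylation in [0.2, 0.5] for hyper (so the doubled level stays ≤ 1) and
  [0.3, 0.95] for hypo (a region can only lose methylation it has).
- **Counts**: expectation = depth_j × methylation × relative coupling +
  background (1.0), with per-sample depths log-normal (σ = 0.15) around the
  depth scale to exercise size factors. `simulate_counts` defaults to
  negative-binomial noise with dispersion 0.05 (MeDIP counts are
  overdispersed); **the default scene uses Poisson noise**. The reason is a
  hard power constraint of the strict |t| > 7 rule with six pairs: under
  overdispersion the paired-t noncentrality for a 2-fold effect is bounded
  by √(6/(5φ)) ≈ 4.9 at φ = 0.05 no matter how deep the sequencing, so no
  depth makes 2-fold effects reliably exceed |t| = 7. The rule is
  calibrated to very deep data where window counts are large and
  near-Poisson after normalization; the default scene reproduces that
  regime. With NB noise the machinery is unchanged but recovering 2-fold
  effects requires a larger threshold-free design or larger folds.
- **Depth scale** (default 400 expected fragments per fully methylated
  median-coupling window): chosen by power analysis, not fitted — the
  noncentrality is ≈ √(2μ) for hyper and ≈ √μ for hypo windows under
  Poisson noise, and |t| > 7 at 5 df needs noncentrality ≳ 10 for ~90%
  power, i.e. expected control counts of order 100 in planted windows.
  This is more per-window depth than a naive genome-size scaling of a real
  study's read budget; it is what the strict fixed threshold requires.
- **Expression**: log2 expression = baseline − coefficient × promoter
  methylation + Gaussian noise per sample, baseline ~ N(6, 1), noise sd 1,
  coefficient 5 — chosen so the planted inverse association has a
  population correlation of ≈ −0.4, the effect size typical of genome-wide
  methylation/expression contrasts in primary cells. 5% of genes are
  silent in both groups; genes whose promoter hosts a planted DMR are
  flagged differentially expressed with probability 0.7 (hyper → down).

What the generator does **not** emulate: subject-level baseline effects
(pairs share no random subject factor; the paired t still applies but its
advantage over an unpaired test is not exercised), fragment-length
variation and GC bias, copy-number structure, repeat content, chromosome-
scale methylation gradients (so the subtelomere contrast on synthetic data
is a null), and read-level sequence error. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated model, not that real libraries are free of these artifacts.

## Numerical and edge-case conventions

- obs/exp is 0 by convention when #C×#G = 0 (then #CpG = 0 too); all-N
  bins report missing values.
- Sequences of ≤ 201 bp cannot contain an island (> 200 bp criterion);
  a single qualifying 200 bp window with no qualifying neighbour fails the
  strict length test and is dropped.
- Window values at exactly the t threshold are not DMRs (strict
  inequality).
- Size factors require at least one window positive in every sample;
  otherwise the error names the remedy.
- Equal-overlap assignment ties resolve by feature precedence; equal
  expression ties resolve by gene id.
- Degenerate variance in the subtelomere or correlation computations yields
  missing P / an error naming the offending sample, never a silent 0.

## Problem sizes

The test suite and the acceptance script run the default scene (2,000
windows, 12 samples, 100 planted DMRs) with 500 permutations; this is the
package's reference configuration and completes in seconds. The permutation
count for real analyses defaults to 10,000 (`RunConfig.permutations`); the
estimator is unbiased at any B, with Monte-Carlo spread shrinking as 1/√B.
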