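# Methods

## Differential-expression model

Expression is compared between two conditions with few (typically three)
biological replicates each. Counts are converted to RPKM with a caller-
supplied effective gene length (genomic span by default; an exonic-union
length can be passed instead — the choice is exposed because published
pipelines differ) and per-sample totals defaulting to column sums. The
per-gene test is a two-sample t-test across replicates, by default the
pooled-variance Student's t on log2(RPKM + 1); Welch and untransformed
modes are available by flag. The log transform stabilizes variance at
three replicates; none of the modes claims bit-compatibility with any
specific commercial pipeline, whose internal test is not public.
Benjamini–Hochberg correction runs across all genes, including those later
removed by the expression filter (filtering is a status, not an exclusion
from testing).

Degenerate variance policy: when both groups have zero variance, p = 1 for
equal means and the smallest positive float for unequal means, with a flag
column rather than silent removal.

Signed fold changes are computed on raw mean RPKM with a configurable
pseudocount (default 0.01) added to both means. The pseudocount tames
division by near-zero means — exactly the regime in which bulk studies
print fold changes in the hundreds or thousands — while leaving
well-expressed genes essentially untouched. With a zero pseudocount and
both means zero the result is a NaN sentinel, never an exception.

The DEG criteria are |signed FC| ≥ 2, q < 0.05, and per-condition mean
RPKM strictly greater than 1 in at least one condition. The developmental
call is threshold-only (|FC| > 2, no test): it mirrors how published
time-course tables that lack replicate-level data are used.

## Six-cluster classification

Normalization divides each gene's condition mean by the arithmetic mean
over the expressed genes of that condition ("expressed" defaults to
mean RPKM > 0; configurable), so the expressed-gene average is exactly 1
and the labels are invariant to rescaling either condition. The six
defined combinations of (direction, below/above average in control,
below/above average in mutant) are C1–C6; the two logically possible but
undefined combinations (a down-DEG rising above average in the mutant, an
up-DEG falling below it) and exact ties at 1 are reported `unclassified`
instead of being forced into a neighbouring cluster, since the six
definitions are exhaustive for the data they summarized, not logically
exhaustive. A normalized value of exactly 0 (a DEG with zero counts in one
condition) counts as below average.

## Concordance statistics

Pearson r between two contrasts' log2 fold changes, p from the t
distribution with n−2 df (scipy's exact implementation of the same
formula). Quadrant counts use strict sign; genes with a log2FC of exactly
0 fall in no quadrant and are reported separately. Per-direction
percentages divide a quadrant count by the number of genes with the stated
x-direction and round half away from zero to one decimal — the convention
that makes 646/707 print as 91.4. The qPCR/RNA-seq validation correlation
is computed on the log2 scale, which avoids the discontinuity of the
signed-FC convention around ±1.

## Genomic proximity permutation test

The statistic is the median (mean available) of distances between
consecutive member TSSs within each chromosome; cross-chromosome pairs are
excluded. TSS = start on +, end on −. The null redraws which genes carry
the member label while keeping every real position fixed: this preserves
the gene-density landscape and is therefore conservative relative to
uniform repositioning. One-sided toward clustering with the +1-corrected
empirical p, so p ∈ [1/(N+1), 1]; N defaults to 1000 and values below 100
are flagged in the result. A Mann–Whitney comparison of observed vs
pooled-null distances is reported as a clearly secondary, non-canonical
output.

## Enrichment and motifs

Term overrepresentation is the standard one-sided upper-tail
hypergeometric test with BH across terms (terms intersected with the
background; terms under 3 background genes skipped). The natural
background is the expression-filtered gene universe. This is a generic
overrepresentation stage; it does not emulate any particular annotation
service's network scoring.

Promoter windows span 500 bp upstream through 100 bp downstream of the
TSS in transcription orientation (600 bp total; the TSS base is position 0
of the downstream segment); windows crossing a chromosome edge are
truncated and flagged. Motif scanning is exact matching on the sense
strand with overlaps counted — IUPAC ambiguity codes are rejected rather
than silently expanded.

## Synthetic-data generator

The generator emulates the statistical structure of the study design:

- **Counts**: negative binomial with Var = μ + α·μ², per-gene baselines
  log-normal around `baseline_mean` (default 100 expected counts,
  `baseline_sigma` = 1 for a realistically wide expression range), 3
  replicates per condition, per-sample library-size factors uniform in
  [0.9, 1.1]. The default dispersion α = 0.01 is the canonical common
  dispersion for genetically identical model organisms — the inbred-line
  regime this design emulates; heterogeneous samples would need a much
  larger value. α → 0 reduces to Poisson.
- **Effects**: a fraction `frac_deg` of genes (default ≈ 7.4%, ≈ 79% of
  them up) gets planted log2FCs: magnitude `min_abs` (1 by default) plus
  an exponential tail capped at 6, with 5% instead drawn uniformly from
  [7, 10.5]. A gene's higher-expressed condition sits at its baseline and
  the other at baseline·2^(−|log2FC|), so extreme fold changes coincide
  with near-zero expression on one side — the pattern seen in real data,
  where the largest printed fold changes come from weakly expressed genes.
- **Companion contrast**: planted log2FCs with expected correlation
  `companion_r` (default 0.55) to the primary ones via
  y = r·z + √(1−r²)·ε on the standardized primary vector; a second count
  matrix is simulated from them and called through the same DE path. The
  empirical r of the generator concentrates within ±0.05 of the target for
  n ≥ 2000. The *measured* cross-contrast correlation is attenuated below
  the planted value by count noise, as it would be in real data.
- **Developmental contrast**: the same construction with `dev_r` (default
  −0.67) restricted to the primary DEGs; non-DEGs get independent noise,
  concentrating the anti-correlation in the regulated genes.
- **Positions**: genes laid down in genome order with 2–6 kb gaps on five
  chromosome arms with Drosophila-like sizes; a fraction of the DEG labels
  (default 0.5) placed in tandem runs of 3–8 adjacent loci, the rest
  scattered, so `cluster_fraction = 0` makes labels independent of
  position.
- **Promoters**: 600-bp motif-free random background with exactly the
  planned number of non-overlapping motif copies planted (junction-created
  extra occurrences are detected with an overlap-aware scan and
  re-sampled). Up-DEGs default to a 15/65/20 mix of 0/1/2 copies,
  background genes 90/10 of 0/1. A small synthetic genome embedding the
  promoters (reverse-complemented on −) supports end-to-end extraction
  tests.
- **qPCR**: CT tables whose ΔΔCT reproduces the planted log2FC up to
  Gaussian CT noise (default 0.1 cycles); **terms**: 30 annotation terms,
  3 of which oversample the up-DEGs 5-fold.

Per-stage seeds derive from the one global seed through
`numpy.random.SeedSequence`, so any stage can be regenerated in isolation
and identical configs give byte-identical outputs.

What the generator does *not* emulate: read-level artifacts (mapping
biases, multi-mapping, 3′ bias), correlated gene-gene expression,
condition-specific library composition beyond a scalar factor, isoform
structure, or any real genome sequence. Passing the calibration suite
therefore demonstrates the statistical machinery is correct and calibrated
under the stated generative model, not that a particular biological
dataset would yield particular numbers.

## Problem sizes and calibration settings

The default configuration mirrors the study scale (13,601 genes, 3 + 3
replicates); a full pipeline run takes a few seconds. The calibration
suite uses 2,000-gene simulations: the null false-discovery check expects
a q < 0.05 fraction ≤ 1%; the recovery check plants 10% DEGs with
|log2FC| ≥ 2 at high expression (baseline 100, tight log-normal spread
σ = 0.25) and expects sensitivity ≥ 0.8 at empirical FDR ≤ 0.10; the
proximity test expects p ≤ 0.01 on fully clustered labels and a uniform p
under the null (fraction ≤ 0.05 within [0.02, 0.09] over 200 repetitions
of 1000 permutations). With three replicates and df = 4 t-tests, power at
exactly 4-fold drops quickly as expression falls — at the default wide
baseline spread (σ = 1) overall sensitivity is nearer 0.5, which is the
realistic regime, and is why the study-scale run calls fewer DEGs than it
plants.

The Pearson-p oracle comparison (t-distribution vs permutation) is made at
panel size 20: for n ≲ 10 the t approximation genuinely departs from the
exact permutation distribution by more than the comparison tolerance,
which is a property of the approximation, not an implementation error.

## Known limitations

- The t-test operates on transformed RPKM, not on a count model; no
  shrinkage of per-gene variances is attempted (by design — the pipeline
  reproduces a t-test/BH workflow, not a negative-binomial GLM one).
- Concordance treats the two contrasts' fold changes as fixed quantities;
  no measurement-error correction of r.
- The proximity null conditions on the real position set; it does not
  model domain-scale structure (TADs) or gene-length effects.
- One TSS per gene; alternative promoters are out of scope.
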