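# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `m6ate`, and what the test suite does and does not
establish about behavior on real data.

## Windowed methylation-event calling

Exons are tiled with contiguous 10-nt windows in genome coordinates; a
terminal remainder shorter than 10 nt is merged into the preceding window
(an exon shorter than 10 nt becomes a single window). Window enrichment is
assessed with a one-sided Fisher exact test whose 2×2 table pits the
window's IP count against the *exon-mean* input count (rounded to the
nearest integer, since the hypergeometric support is integral), each over
the sample's total exonic reads. Using the exon mean as the control cell
makes the test robust to window-scale input fluctuations at the cost of
assuming roughly uniform input coverage within an exon — true for the
synthetic data, approximately true for real input libraries.

The exact tail probability is computed by a vectorized recurrence: the
log-pmf at the observed count via `gammaln`, then multiplicative term
ratios along the upper tail, stopping when terms fall below 1e-15 of the
accumulated sum. This is exact (it matches `scipy.stats.fisher_exact` to
~1e-12 relative in the tests) and stays fast for genome-wide margins of
~1e8 reads, where generic hypergeometric survival functions are orders of
magnitude slower.

P-values are Benjamini–Hochberg adjusted across all windows of a sample
(`statsmodels.stats.multitest`), and the significance threshold is applied
to the *adjusted* values. Runs of adjacent significant windows are joined
within exons only — runs never cross exon boundaries, consistent with
windows being defined per exon. Runs of at least 90 nt become events; runs
longer than 200 nt are split into consecutive 200-nt events from the
transcript 5′ end (genomic right on the minus strand), and a terminal
remainder is kept only if it is itself at least 90 nt, consistent with the
90-nt event minimum.

The threshold tuner evaluates the event count at each grid value (38
log-spaced thresholds, 1e-03 to 1e-40, one per decade) and returns the
value whose count is closest to the target (10,000 events per sample by
default), breaking ties toward the more permissive threshold and emitting
the full count-vs-threshold table. If no threshold produces any event, the
most permissive value is returned with a warning flag.

For small synthetic cohorts, where tuning to 10,000 events is meaningless,
event calling uses the fixed adjusted-p threshold 1e-03 — the most
permissive value of the calibration grid, still FDR-controlled at 0.1%.

## Translation efficiency

RPKM = count / (gene_length/10³) / (library_size/10⁶), with library size
the total retained exonic reads. TE = log2(RPKM_polysome / RPKM_total).
Genes under 2 RPKM in a total-RNA library are flagged not-retained in that
condition, and a transcript enters Δ computations only if retained with
finite TE in all four libraries of a pair — the symmetric retention rule
avoids undefined ratios without imputation. Retained genes with zero
polysome signal carry a −inf sentinel and are excluded from rank
statistics; no pseudocounts are used for TE, because a pseudocount would
silently shift percentile ranks. (The total-RNA log2 fold change helper
does use a pseudocount of 1; it feeds only the abundance-vs-Δm6A
correlation, not the ranking.)

Note one intrinsic property of ratio normalization: if a sizable fraction
of the transcriptome shifts its polysome association in one state, the
library total shifts with it and every gene's normalized TE moves by the
same constant. Percentile ranks — the quantity the filter cascade actually
consumes — are invariant to that common shift. Absolute recovery of a
planted TE effect is unbiased only when few genes change, which is the
regime the parameter-recovery tests use (~2% of genes shifted) and the
standard assumption of un-spiked RNA-seq normalization.

## Integration and the filter cascade

Δm6A per transcript is the difference of group means of called event
counts (DGC − GSC); classification uses inclusive cutoffs at ±1.
Percentile ranks of ΔTE use average ranks for ties, scaled to
100·rank/n, and are computed over TE-retained transcripts. The per-pair
candidate rule is `te_rank_pct ≥ 70 AND (gsc_peaks − dgc_peaks) ≥ 2` with
raw per-sample event counts; the common set intersects the per-pair sets
over all pairs, excluding (with a warning) genes absent from any pair.
Percent-peak-loss bins place both boundaries in the middle bin:
[0, 50) → A, [50, 75] → B, (75, 100] → C. Group TE comparisons use the
two-sided Wilcoxon rank-sum test, exact when there are no ties.

## Motif and miRNA analysis

RRACH scanning returns all, possibly overlapping, 5-nt matches of
`[AG][AG]AC[ACU]` on the sense strand of the spliced transcript.
Seed complementarity uses the 7mer-m8 frame: the Hamming distance between
the 7-nt site sequence and the reverse complement of miRNA positions 2–8,
accepted at ≤ 1 mismatch. Sites spanning a region boundary are classified
by majority overlap, ties toward the 5′ region, so a site split evenly
across the stop codon counts as CDS. The expression screen keeps miRNAs
with fold change ≥ 4, boundary inclusive. A *candidate* miRNA must pass
both the expression screen and the seed check at ≥ 1 site lying inside a
called event in every sample — screen first, overlap second.

## PLA spot counting

Grayscale conversion (luminance weighting for RGB input, preserving the
intensity scale), Gaussian smoothing (σ = 1.5 px), adaptive mean threshold,
8-connected component labeling, and a 2-px minimum component size.
The adaptive rule marks a pixel foreground when the smoothed intensity
exceeds its local-window mean (31 px, held constant across a batch so
control and experimental images are processed identically) by a fixed
offset. The offset default is 8 intensity units: after σ = 1.5 smoothing,
additive noise of σ ≈ 5 has residual σ ≈ 0.9, so 8 units sits ≈ 9 noise
standard deviations above background — blank images reliably yield zero
components — while planted spots (amplitude 150 before smoothing, ≈ 95
after) clear it by an order of magnitude. Counts are invariant under
moderate affine intensity rescaling (tested at 0.6×–1.5×); an extreme
downscaling that pushed spot amplitude toward the absolute offset would
break this, which is inherent to any fixed-offset adaptive threshold.
Cell counts are an input; dots-per-cell is a division, undefined at zero
cells.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not raw
sequencing reads: no fragment-length, GC, or sequencing-error models.

* **Geometry.** 300 transcripts by default, 1–3 exons of 1000–2500 nt on
  eight synthetic chromosomes, 20% minus-strand, CDS at 10–20% to 75–90%
  of transcript length. Three peaks per transcript are planted
  window-aligned within single exons, 100–200 nt, separated by ≥ 2
  background windows so distinct peaks cannot merge into one run.
* **Counts.** Input window counts are NB(mean = 50, size = 20); IP counts
  are NB(50·enrichment, 20) inside carried peaks (8× by default). Size 20
  at the 10-nt-window scale corresponds to a ~26% coefficient of
  variation. Gene-level expression counts use a larger size (50): gene
  counts aggregate thousands of positions, so their relative dispersion is
  lower. Total-RNA means are lognormal around 500 reads (log-sd 0.5) and
  equal across states for 95% of genes.
* **Coupling.** Each planted peak is absent from every differentiated
  sample with probability 0.2; transcripts losing ≥ 2 peaks form the
  loss set, and a configurable fraction of them (default all) receives a
  +2 log2 TE shift in the differentiated state. The expected common set is
  exactly the coupled set.
* **Sequences.** Random RNA with RRACH content controlled by
  scrub-and-plant: motifs outside allowed regions are destroyed by
  randomized slot-invalid substitutions (randomization avoids rewrite
  cycles), ≥ 1 motif is planted inside every peak (10/kb inside peaks,
  2/kb background by default). Planted miRNA sites are 7-mers containing
  an RRACH, implanted inside peaks, with the miRNA seed constructed as the
  site's reverse complement plus a configured number of mismatches; decoy
  sites avoid RRACH and peak interiors, and decoy miRNAs draw expression
  fold changes below 4.
* **Images.** Gaussian blobs (σ = 2 px, amplitude 150 over background 20)
  with enforced minimum centroid separation and additive Gaussian noise
  (σ = 5).
* **Determinism.** Every generator is a pure function of (config, seed),
  with one RNG stream per generator derived from the master seed at fixed
  offsets — per-sample streams for MeRIP counts, so any subset of samples
  is bit-identical to the full run.

The threshold-calibration study uses a dedicated configuration: 2500
transcripts of two 2000–3600 nt exons, five peaks each (12,500 planted
regions per sample, on the order of 10⁴) with per-peak enrichment uniform
on 2×–16× and no peak loss, six samples from one cohort. Across that
enrichment range the number of detectable events sweeps through the
10,000-event operating point as the threshold grid moves from 1e-03 to
1e-40, which is what makes the tuner's selection informative; tuned counts
land within ~2% of target (~9,800–9,850 per sample at the sizes above,
~1.4M windows per sample, about a minute for all six samples on one CPU).

## What passing tests do and do not show

Recovery, calibration, and cascade tests certify the pipeline's internal
consistency: the caller finds what the generator planted, the tuner hits
its operating point, the cascade returns exactly the planted common set
under strong coupling (20/20 seeds at 12× enrichment) and essentially
nothing under zero coupling. They do not certify behavior under features
the generator omits: non-uniform input coverage within exons, isoform
mixtures, positional fragment biases, batch effects between samples, or
antibody-specificity artifacts in MeRIP. The brute-force oracles
(hypergeometric tail enumeration, hand BH step-up, pure-Python run-length
caller, regex motif scan, exhaustive 4⁷ seed enumeration, exact Wilcoxon
permutation tail) certify the numerical kernels independently of the
implementation paths they check.

## Degenerate inputs and tie-breaks

Empty p-vectors, empty sample groups, zero-variance correlation inputs,
zero-cell images, and windows exceeding sample totals raise errors rather
than returning silent defaults. Thresholds are open intervals (p <
threshold); rank and fold-change cutoffs are inclusive (≥). The tuner's
tie-break is toward the permissive threshold; region classification ties
break toward 5′; BH ties are order-preserving.
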