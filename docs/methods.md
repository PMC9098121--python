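# Methods

This note documents the models, parameter choices and numerical rules
behind `ttquant`, and what the synthetic study conditions do and do not
establish about real data.

## Coordinate and signal conventions

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based closed GTF convention happens only in the readers/writers.
"Standard chromosomes" is a configurable allow-list defaulting to
autosomes + X + Y. All statistics use sense-strand signal oriented 5′→3′
in transcription direction; antisense signal is never mixed in. Coverage
is stored as per-strand binned depth vectors; bedGraph (one file per
strand) is the exchange format, with adjacent equal-value bins merged on
write and zero runs omitted. The representative transcript of a gene is
chosen by best (lowest) support level, then largest genomic width, then
lexicographically smallest transcript id — a deterministic,
permutation-invariant rule; the final tie-break is a convention the
annotation itself does not supply.

## Synthetic study conditions

The generators encode the signal regimes the statistics are designed
for; their defaults are the package's study conditions and are not tuned
per analysis.

- **Gene set**: two genes per width stratum (<15, 15–30, 30–60, 60–90,
  90–120, ≥120 kb; widths uniform within stratum, the open-ended top
  stratum capped at 200 kb), alternating strands, 3–8 exons of
  150–400 bp, intergenic gaps of 30 kb. Sequences are uniform-random
  ACGT scrubbed so that U1/PAS motifs occur *only* where planted
  (default 2 of each U1 motif and 3 PAS per gene, in intron 1 or later),
  with a canonical ATG 30 bp into exon 1. Planted counts are exact by
  construction, which is what lets motif-scanner tests assert equality
  rather than bounds.
- **Coverage**: basal depth 10 reads/bp with Poisson noise per bin
  (bin 50 bp) — nascent-RNA depth is count-derived, so Poisson is the
  natural bin-level noise; negative-binomial noise is reserved for exon
  count matrices where biological replicate dispersion matters
  (variance = μ + 0.05 μ²).
- **Heat-shock attrition**: expected HS depth at distance *d* kb beyond a
  10 kb onset is `basal · (1−h)^(d−10)` with hazard h = 0.05/kb — a
  constant per-kb premature-termination probability. The closed form
  gives the expected 3′/5′ ratio-of-ratios per gene width, used as the
  oracle for the processivity statistic.
- **DRB waves**: the released pause cohort travels as a Gaussian pulse
  centred at `v·t` (amplitude 4× basal) with the refilled gene body
  rising behind it, its edge trailing the pulse by two front widths. A
  pure smeared step would be monotone and have no interior maximum for a
  spline peak to track; the pulse is the explicit model of the cohort
  the wave-peak method follows. At t = 0 the pulse sits at the promoter,
  which anchors the t = 0 wave position.
- **FP waves**: depth = `basal · Φ((d − v·t)/σ)`; the rear edge's
  half-height sits exactly at `v·t` (Φ(0) = ½).
- **Front smearing**: σ grows with distance travelled,
  `σ(t) = front_sd + cv·v·t` with front_sd = 2 kb and cv = 0.10,
  modelling cell-to-cell elongation-rate variability. This is also what
  makes the FP inflection slope shallower at higher speed for equal
  time, the qualitative comparison the rear-slope method reports.
- **Spike-ins**: a second gene set with constant true abundance,
  perturbed only by per-sample library factors (1.0, 2.0, 0.5, 1.25) to
  be recovered.
- **First-exon effect**: under HS the first-exon NB mean is multiplied
  by θ (default 4) with remaining exons unchanged, so the true per-gene
  log2 ratio-of-ratios is log2 θ.

What the generators do *not* emulate: mappability and GC bias, splicing
junction reads, antisense/bidirectional promoters, overlapping genes,
replicate-level batch structure, and annotation errors. Passing tests
therefore demonstrate correctness of the estimators under their stated
model, not robustness to those real-data artefacts.

## Wavefront estimation

Smoothing uses a penalised cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`); the penalty defaults to
generalised cross-validation, under which a noisy Gaussian-CDF edge at
n = 1000 bins is recovered within 5% of its amplitude (tested). The
penalty is exposed because any fixed smoothing constant is meaningful
only relative to an implementation's basis. Derivatives are evaluated
analytically from the spline, never by finite differences on noisy data.

DRB wave peaks are spline maxima per timepoint, restricted to positions
at or beyond the previous peak (waves advance); a restriction that
changes the argmax sets a flag. The t = 0 peak is anchored in the
promoter region (first 2 kb). Flat maxima resolve leftmost. FP
half-height positions guard against residual promoter spikes by starting
the upward search after the last position where density is below ¼ of
the windowed maximum (window 150 kb); crossings are interpolated
linearly between bins. Rates are ordinary least squares of position on
time; per-gene FP rates are averaged and reported to one decimal with
half-up rounding (ties away from zero), values first snapped to nine
decimals so float representation error cannot flip a tie.

## Ratio statistics

Travel ratios add 1 to promoter and body *counts* before converting to
densities, so zero-coverage genes yield finite ratios; the pseudocount
can be disabled, restoring exact scale invariance. The processivity
statistic instead discards genes with any zero-count interval (the
retained and discarded sets partition the input, with reasons recorded).
Interval boundaries at fractional bp are rounded inward. Stratum
boundaries are half-open [lo, hi), so a 15,000 bp gene belongs to
15–30 kb. The readthrough downstream window overlapping another
same-strand gene flags the result rather than excluding it, keeping the
definition intact while making the confound visible.

## First-exon enrichment and DE calling

The statistic is log2 of the ratio-of-ratios of size-factor-normalised
means with +0.5 on each of the four cell means (disabled in exact
worked examples); the same per-sample factor applies to both paired
columns, so the statistic is invariant to per-sample scaling. Inference
is pluggable: the default permutes condition labels on the
per-replicate log2(first/remaining) ratio, enumerating all assignments
when feasible (Monte Carlo beyond 2×10⁵) and including the observed
labelling in the reference set; a Welch t alternative exists. With three
replicates per condition the label-swap symmetry caps the two-sided
permutation p at 0.1, so calibration studies use five per condition
(252 assignments), where the empirical type-I error at α = 0.05 is
0.05 ± 0.02. BH is the multiple-testing correction throughout. The
shift summary reports the positive-logFC fraction over all tested genes
and, separately flagged, over the significant subset. DE calls on
3′-half counts use a normal-approximation Wald test on log2 normalised
counts; this is a deliberate replacement for shrinkage-based DE
machinery, since the downstream thresholds (|FC| ≥ 2, FDR ≤ 0.01, base
mean ≥ 10) depend on the fold-change and a usable p, not on dispersion
shrinkage.

## Sequence features and peptides

Motif occurrences are counted overlapping (step 1); undercounting tiled
U1 motifs would bias the U1/PAS ratio downward. The PAS denominator is
AATAAA; genes with zero PAS are excluded from ratio summaries and
flagged. Motif counting operates on the pre-mRNA interval TSS..TES (an
mRNA mode can be composed from exon intervals). Readthrough translation
starts at the canonical ATG in exon 1, runs across the exon 1/intron 1
junction in frame, and stops at the first stop codon, capped at the
transcript end so stop-free frames terminate with `stop_found = False`.
Digestion cleaves C-terminal to K/R except before P, zero missed
cleavages by default, minimum fragment length 7.

## Limited-pool simulator

State is (free pool, per-gene engaged polymerases); events are
initiation attempts (Poisson, rate `c · free_pool` per gene copy,
redrawn after every event — exact for a piecewise-constant rate by
memorylessness) and deterministic terminations. An attempt succeeds only
if the pool is non-empty and the previous initiation on that gene is at
least one footprint (50 bp, i.e. 1.5 s at 2 kb/min) downstream; this
dead time prevents unbounded promoter density. Polymerase number is
conserved and checked at every event. The premature switch truncates the
termination time of every polymerase still upstream of the 10 kb site;
polymerases already past it run to the normal end, so the body empties
after exactly one transit of the remaining length. The site applies to
all classes; on the 5 kb gene it lies beyond the end and is inert.

Calibration targets a 2.5 s mean inter-initiation interval per gene
copy at baseline equilibrium. Successful initiations form a
dead-time-thinned Poisson process, so the closed form is
`c = 1/((τ − d)·F)` with d the footprint dead time and F the equilibrium
free pool from Little's law (`engaged = Σ transit_g / τ`); geometric
bisection against simulated means (tolerance 1%) refines it. Defaults —
two copies each of 5/63/100 kb genes, pool 10,000, speed 2 kb/min —
put ~4,000 polymerases in genes at baseline, leaving a large free pool
so the fixed-point argument is accurate, and a measurement window of
1,500 s after a burn-in of 1.2 longest transits (~3,600 s) gives ≈0.4%
Monte-Carlo error on the mean interval over 100 runs. Density summaries
report run-averaged counts per position bin on an arbitrary but
run-consistent scale; only the dynamics, not absolute densities, are
interpretable.

## Problem sizes

Test and example runs use the generator defaults above: 12–36 genes for
coverage statistics, three 220 kb genes for wavefronts, 200 genes for
effect-size recovery, 2,000 genes for null calibration, and 100
simulator runs — sizes chosen so every statistic is estimated with
Monte-Carlo error comfortably below the tolerance it is tested at.

## Known limitations

- The DE caller's normal-approximation p-values are anti-conservative
  for very low counts; the base-mean filter is the guard.
- Per-gene DRB rates are out of scope: the wave-peak method is defined
  on meta-profiles; genome-wide FP rates are likewise limited to the
  per-gene half-height procedure on well-expressed long genes.
- bigWig is not written; bedGraph is the exchange format.
- The simulator omits stochastic elongation, pausing along the gene
  body and collision dynamics beyond the initiation footprint; it is a
  minimal model of pool-limited re-initiation, not of elongation
  kinetics.
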