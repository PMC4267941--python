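# Methods

This note documents the models implemented in `dielcycle`, the defaults
chosen where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the numerical conventions that
affect results.

## Study design and data model

The package targets diel (light/dark-entrained) expression time courses.
The reference design, encoded in `SamplingLayout`, is 8 samples per day at
3-h intervals (ZT 0…21) under 12 h light : 12 h dark, with two biological
replicates appended as two consecutive 24-h days — a 16-column matrix per
gene. Any layout whose day length is an integer multiple of the sampling
interval is supported (e.g. 4-h sampling over three days). Expression
values are nonnegative FPKM-like quantities; samples are equalized by
upper-quartile normalization (each column scaled so its 75th percentile
over nonzero genes matches the mean of the per-column quartiles).

## Cyclic score

Each day-length window of M consecutive samples is mean-centred and
discrete-Fourier-transformed; the squared magnitudes |y_k|² for
k = 1…⌊M/2⌋ form the window's power spectrum. Each window's spectrum is
min–max normalized to [0, 1] and the normalized spectra are averaged
across windows; the cyclic score is the averaged value at the day-length
(24-h) component.

Numerical conventions, and why:

- **Mean-centring / DC exclusion.** Without removing the k = 0 component
  the DC term dominates the normalization denominator and no gene could
  reach a score of 1; with it, a clean diel cosine scores exactly 1, which
  anchors the score's interpretation (confident cyclers saturate at 1).
- **Window set.** All day-length subsets are used, stepping one sample at
  a time (9 windows for the 16-point design). Averaging over every subset
  means no particular subset biases the estimate, and it is required for a
  well-behaved null: with only two or three windows the probability that a
  *random* permutation puts its spectral maximum at the 24-h bin in every
  window is 3–7%, so the null score distribution has an atom of that mass
  at exactly 1 and no top-1% or top-2% quantile below 1 exists. With nine
  windows the atom shrinks below 1% and the percentile thresholds are
  informative. The window step (as an overlap fraction) remains a
  configuration knob; so does using |y_k| instead of |y_k|².
- **Constant vectors** score 0 (their normalization is undefined and a
  constant gene cannot cycle); a constant *window* contributes an all-zero
  normalized spectrum.
- The score is invariant to affine transforms a·x + b (a > 0) of the
  input: centring removes b, min–max normalization removes a.

## Permutation null and calling

The null is built by repeatedly drawing a gene row and permuting its
values uniformly over sample positions, then scoring. The cycling
threshold is the k-th largest null score with k = ⌈n·p/100⌉ for a top
percentile p (default 2), so a fraction p/100 of the null itself is at or
above the threshold and the empirical false-positive rate of the call is
calibrated at p/100. The "top second percentile" reading (rather than the
2nd conventional percentile) is forced by monotonicity: stricter
percentiles must give higher thresholds. Per-gene empirical p-values are
add-one smoothed, (r+1)/(n+1), so p is never exactly 0.

## Period, amplitude, phase

Fits use the full-length (all N points, span T) mean-centred spectrum.
The dominant component k* (k ≥ 1) gives a raw period T/k*; a quadratic fit
to log-power over (k*−1, k*, k*+1) shifts the peak off the integer grid
(skipped at the spectrum edges or when a neighbour's power is numerically
zero; the shift is clamped to ±½ bin). Interpolation is needed because the
16-point grid only offers periods 48, 24, 16, 12… h, while real fitted
periods form a continuous distribution around 24 h. Amplitude is
2|y_k*|/N — exact for a pure cosine — and phase is the ZT at which the
fitted cosine peaks, mapped into [0, day length). Phase *clusters* are
coarser: the appended days are averaged per ZT and the cluster is the ZT
of the maximum, ties broken toward the earlier ZT.

## Phase subclustering

Within each phase cluster, min–max-normalized profiles are partitioned by
k-means (Euclidean distance) in two rounds: round 1 with k = ⌈n/60⌉
(target mean size 60, the midpoint of the 10–90 size band), then any
cluster above the upper bound is re-clustered once with the same rule.
Clusters below the lower bound are merged into the nearest surviving
centroid. k-means uses multiple seeded restarts keeping the best
within-cluster sum of squares (scikit-learn's Lloyd implementation).
Display ordering uses average-linkage hierarchical clustering leaf order.
The target size, size band, restart count and distance (correlation
distance optional) are configuration knobs; the literature this design
follows does not fix them.

## Enrichment

Term enrichment is Fisher's exact test on the 2×2 membership table, with
Benjamini–Hochberg adjustment applied within one family per phase cluster
(phases are reported separately, so each cluster's term family is
adjusted on its own; a joint family is available). Backgrounds: the whole
genome for "cycling overall" tests, all cycling genes for per-phase tests
(mirroring the promoter-motif background). Underrepresentation uses the
opposite one-sided alternative. Multi-phase enrichments are classified as
adjacent when the enriched ZT bins form a consecutive run on the circular
day (ZT 21 and ZT 0 are neighbours). Functional-group matrices average
−log10 of the raw p across each group's terms per phase.

## Duplicate divergence model

Pairs are binned by Ks with half-open bins [i·w, (i+1)·w), w = 0.3, and
one model step corresponds to one bin. The three-state update on
f = (f_CC, f_NN, f_D) is

    f_CC′ = f_CC(1−d) + α·s·f_D
    f_NN′ = f_NN(1−d) + (1−α)·s·f_D
    f_D′  = f_D(1−s) + d(f_CC + f_NN)

with a single divergence rate d for both identical states and a single
reversion rate s, split α : 1−α between CC and NN on reversion. The
reversion split is not identifiable from state frequencies alone and
defaults to the symmetric α = ½, consistent with finding no evidence of a
differential divergence rate. Under α = ½ the gap f_CC − f_NN contracts
by (1−d) each step, which yields the closed-form fit from two consecutive
bins,

    d = 1 − (f_CC′ − f_NN′)/(f_CC − f_NN),
    s = [f_D − f_D′ + d(1 − f_D)] / f_D,

an exact algebraic inverse of the update wherever identifiable
(f_CC ≠ f_NN and f_D > 0; degenerate inputs raise, out-of-range fits are
clipped with a warning — fitting near the stationary point is intrinsically
ill-conditioned because the frequency change tends to 0). The stationary
diverged fraction is d/(d+s) (≈ 0.442 at d = 0.42, s = 0.53).

Retention significance uses randomization: the second gene's attributes
are shuffled across pairs (phases shuffled among co-cycling pairs only for
the phase statistic), with Z = (obs − null mean)/null SD and a two-sided
add-one-smoothed empirical p. Phase differences are circular (max 12 h on
a 24-h day); phase-shift enrichment is observed/expected counts under
random re-pairing, with an OLS line of enrichment on |Δphase|.

## Ortholog comparison

Cycling-state association between species uses a 1-df chi-square on the
2×2 co-cycling table without continuity correction (configurable);
percentages are reported to one decimal. Amplitude agreement is Pearson
r² on log amplitudes (unit-free across species); phase agreement is
Pearson r² on raw ZT values — deliberately linear, to match the field's
common reporting — with the Jammalamadaka–SenGupta circular correlation
alongside as the statistically preferable diagnostic for angles.

## Promoters, motifs and classifiers

Promoters are the ≤1-kb region immediately upstream of the TSS, truncated
where they overlap another annotated gene body, reverse-complemented for
minus-strand genes, and dropped below 50 bp. Coordinates are 0-based
half-open internally; GFF3 is converted at the boundary.

PWM scanning uses log-odds scores (base 2) against a 0-order background
with a 0.01 pseudocount per cell. The score threshold for a target
p-value (default 1e-5 per site) is exact: the distribution of the score of
one random background L-mer is computed by dynamic programming over
integer-discretized scores (granularity 1e-3 bits, so the total rounding
error of an L-mer score is below L/2000 bits), and the threshold is the
smallest score whose tail probability is ≤ p. Scanning reuses the same
integer scores, so the calibrated tail applies to the scanner exactly;
motifs too short or degenerate to attain p raise an explicit error. Both
strands are scanned; presence is ≥1 hit.

Redundant motifs are merged by UPGMA on distance 1 − (best-offset mean
column Pearson correlation), requiring ≥4 aligned columns, cutting the
tree at distance 0.25, and replacing each group by its position-wise
average PWM at the best offsets. An enumerative k-mer Fisher-enrichment
finder is included as a deliberately simple seed-motif discovery step.

Each motif is assigned the phase cluster where its presence is most
significantly enriched (minimum adjusted p, ties to the earlier ZT). The
naive classifier scores a gene by its count of that phase's motifs — the
count gives a usable ranking for AUC, while the F-measure operating point
is the literal ≥1-motif rule. The SVM classifier is a linear max-margin
model on the presence matrix with a grid over the penalty C
(0.01…2.0) and the training negative:positive ratio R (0.25…4),
implemented by seeded subsampling of negatives within each training fold
of a stratified 10-fold cross-validation; the grid cell with the best mean
held-out AUC is reported, with nonzero feature weights from a final fit.
AUC is computed as the tie-corrected rank statistic U/(n⁺n⁻), identical
to trapezoidal ROC integration. Cluster surveys run the SVM once per
cluster (positives = cluster, negatives = remaining genes, minimum 8
positives) and count clusters above an AUC threshold (default 0.7)
together with the fraction of cycling genes they cover.

## Synthetic data

`generate_expression` draws gene means log-normally (log10 mean 1.0,
sd 0.5), builds cycling genes as mean·(1 + a·cos(2π(t − φ)/period)) with
a = 0.5 by default — so amplitude is exactly half the mean, and amplitude
and mean are strongly correlated across genes — and applies unit-mean
multiplicative lognormal noise (CV 0.1 by default), independently per
observation; the two days are therefore independent noisy replicates of
one underlying curve. Phases follow a mixture of 40% near dawn (wrapped
normal at ZT 0, sd 1.5 h), 30% near dusk (ZT 12) and 30% uniform — a
qualitative match to the bimodal dawn/dusk phase distribution of diel
transcriptomes; the exact proportions and spread are free choices.
Noncycling genes are flat (an optional per-day linear drift is available
but off by default, since the fraction of trending noncyclers in real
data is unknown).

`generate_duplicate_pairs` evolves each pair's state through the
three-state Markov chain (i steps for bin i) from configurable initial
frequencies, and couples co-cycling phases through a shift kernel
defaulting to P(0) = 0.4, P(±3 h) = 0.2 each, remainder uniform.
`generate_promoters` plants exact consensus sites into i.i.d. background
sequence of given GC content at a per-gene plant frequency.
`generate_annotations` builds phase-linked terms (90% of members from one
phase bin by default) plus uniform background terms.

What the generators do **not** emulate: read-level sampling noise and its
mean–variance structure, zero inflation of lowly expressed genes,
correlated noise between genes, trends across days, promoter sequence
composition beyond 0-order GC, and degenerate (non-consensus) motif
instances. Passing tests on these data therefore demonstrate correctness
of the algorithms under the stated generative assumptions, not
performance on any real transcriptome.

## Problem sizes and determinism

Default analysis sizes were chosen so every routine is exercised at
statistically meaningful scale while a full test run stays lightweight:
10,000 permutations for null calibration, 1000 cyclers for score
saturation, 500+500 genes for period recovery, thousands of pairs per Ks
bin for model-trajectory checks. All randomness flows through
`numpy.random.default_rng` seeded per call; identical seeds give
bit-identical outputs, and the pipeline writes its seed and thresholds to
a JSON manifest next to the outputs.

## Known limitations

- The closed-form rate fit assumes α = ½; other splits require numerical
  fitting, which is not implemented.
- Period interpolation is biased slightly upward (Jensen effect of
  period = T/k on a symmetric error in k), on the order of 0.05 h at
  noise CV 0.1.
- Scanning reports per-site significance only; no promoter-level
  multiple-testing correction is applied to hit counts.
- The SVM grid search reports the best cell's cross-validated AUC, which
  is optimistically biased by selection; a nested evaluation is left to
  the caller.
- GO-style annotation is taken as given (no ontology graph propagation).
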