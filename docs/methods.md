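# Methods

This note documents the analytical conventions, synthetic-data model,
numerical choices and known limitations of the package. Everything here
is computed by the code and its test suite; nothing is an external claim.

## Peri-tone alignment and z-scoring

Traces are assumed regularly sampled (default 10 Hz) with no missing
frames. Bins are half-open 1-s intervals `[onset + b, onset + b + 1)`
with bin 0 starting at tone onset; bin edges are converted to sample
indices by rounding, so onset times that are not exact frame multiples
are absorbed to the nearest frame. Trials are averaged into blocks of 2
in presentation order; a trailing unpaired trial is dropped with a
warning. The pre-tone z-transform uses each neuron × block's own 15
baseline bins with the unbiased (n−1) SD — at n = 15 the biased/unbiased
difference is immaterial scientifically but must be pinned for exactness
tests. A zero-SD baseline (constant synthetic neuron) yields z = 0 with a
flag rather than an error so batch runs survive degenerate units. The
baseline statistics are computed from the 15 one-second *bins*, not from
raw frames.

The whole-session z (input to the preference index) averages the first 2
presentations of a tone type at frame resolution, z-scores that average
against the neuron's whole-session mean/SD, and averages over the 15 tone
seconds, producing one scalar per neuron per stimulus.

Both transforms are invariant to per-neuron affine changes of the raw
trace (positive gain and offset), which the property tests assert.

## Response classification and taxonomy

A tone-period z trace is (+)responsive when two consecutive bins are
strictly above +3, (−)responsive when strictly below −3. The threshold is
strict (a bin at exactly 3.0 does not qualify). Three conventions the
classification rule itself does not determine:

- *Both patterns in one trace* — the qualifying pair with the larger mean
  |z| decides the label.
- *Blocks disagreeing in sign* — a neuron's label comes from the
  qualifying pair with the largest mean |z| across blocks; a neuron is
  responsive if any block qualifies.
- *Tone-period bins* are 0..14 inclusive of the onset bin.

Headline proportions are classified on blocks of 2; a per-trial mode
(block size 1) exists for the consecutive-tone stability analysis, where
a neuron counts as stable iff it is responsive on two adjacent
presentations of the same tone type. Spontaneous events reuse the same
excursion rule (≥ 2 consecutive bins above +3 of the window-normalized
binned trace, one count per maximal excursion) for internal consistency,
since no separate event definition is canonical for this pipeline.

Group comparisons of type membership use the two-sided Fisher exact test
on the 2×2 table {in type vs not} × {group A vs B}.

## Preference index

`|Z_NT − Z_CS⁺| / (|Z_NT| + |Z_CS⁺|)`, signed by which stimulus has the
larger absolute response. Two degenerate cases are flagged rather than
guessed: an exact tie |Z_NT| = |Z_CS⁺| returns signed value 0 with the
magnitude recorded separately (so histograms are unaffected by an
arbitrary sign), and a zero denominator returns 0. Reporting histograms
use 20 equal bins on [−1, 1]. Distributions are compared with the
two-sample KS test using the asymptotic p-value, appropriate at the
hundreds-of-neurons scale the pipeline targets.

## Clustering

Concatenated NT-then-CS⁺ z-traces are passed through the saturating
linear map [−5, 5] → [−3, 3] (values outside saturate), which caps the
influence of very large excursions while preserving response shape. Ward
linkage with Euclidean metric is computed by scipy; the test suite checks
the full merge tree against an O(n³) Lance–Williams reference at n = 12.
The dendrogram is cut at `frac × max merge height` (default frac = 0.05)
applied to raw (unnormalized) heights — merges strictly above the
threshold are removed; cluster mean profiles are computed from the
*unscaled* z-traces. Cutting is monotone: smaller frac never yields fewer
clusters. At realistic noise levels a 5% cut fragments noisy
non-responsive neurons into many small clusters; this is a property of
the threshold, not a defect, and the cluster report (per-cluster type
composition and segment peaks) is the intended reading aid.

## Population geometry

Each group contributes a matrix with time bins as rows (NT tone bins then
CS⁺ tone bins; per-neuron mean block traces) and neurons as columns. The
larger group is subsampled without replacement — with a required, logged
seed — to match the smaller, and the two matrices are stacked along the
*time* axis, pairing matched columns. This row-wise stacking is what
makes size matching necessary and gives each group × stimulus segment its
own trajectory after projection; PCA treats time bins as observations and
neurons as features (mean-centered, SVD). Variance fractions are reported
for all components.

Mahalanobis separation measures each NT-bin point against the CS⁺ bins'
mean and covariance with shrinkage `Σ + λI, λ = 10⁻³·tr(Σ)/K`, which
guarantees invertibility when the bin count barely exceeds (or falls
below) the dimensionality K = 15; for well-conditioned covariances the
perturbation is < 0.1%, and tests of the identity-covariance reduction
(Mahalanobis = Euclidean) disable shrinkage to make the reduction exact.
When the number of reference bins is ≤ K the raw covariance is singular
and distances are dominated by the regularizer scale — absolute distances
are then only comparable between groups analysed with identical bin
counts and K, which the pipeline enforces. The asymmetric convention (CS⁺
cloud as reference) is the default; a symmetric average is available.
Group comparison of per-bin distance vectors uses a two-sample t test
with df = n_binsA + n_binsB − 2. Both distance series are invariant to
orthogonal rotations of the component basis.

## Behavior

Freezing percent is the fraction of binary frames in a half-open
interval × 100. Per-tone percents are averaged in blocks of 2 with a
trailing singleton *kept* (with a warning) because cue sessions
legitimately present odd tone counts. The generalization index is the
ratio neutral/reference freezing (1 = full generalization); the
difference variant is available behind a flag because the ratio/difference
choice is a genuine open convention — the ratio is the default because
the index is described relative to reference freezing. A zero reference
makes the ratio undefined, returned as a flagged `None` rather than
infinity.

## Photometry

ΔF/F is computed by least-squares fitting the isosbestic channel to the
sensor channel over the whole session and taking (signal − fit)/fit; this
cancels shared gain, motion and slow-bleaching artifacts while sensor-only
transients survive, and is invariant to a common multiplicative gain on
both channels. A zero-variance isosbestic falls back to session-median
F₀ with a flag. Downsampling uses non-overlapping window means with a
truncated trailing partial window. Per-trial z uses each trial's own 2-s
pre-tone baseline (unbiased SD at frame resolution). Trials are pooled by
elicited freezing with strict inequalities: > 75% high, < 25% low,
boundary trials excluded; an empty pool is flagged, not fatal.

## Human analyses

Startle standardization divides each subject's per-cue mean peak-to-peak
EMG by their mean ITI startle within the phase (phase-specific ITI
trials; the subtraction variant is behind a flag). At recall the first 4
trials per cue form the generalization test; generalization =
standardized(CS⁻) − standardized(CS⁺). Standardized scores are invariant
to any per-subject multiplicative gain. Endocannabinoid baselines are the
natural log of the mean of two positive time-point values; the log base
affects slope units but no correlation-based conclusion. The association
is Pearson's r with its two-sided p, plus a percentile CI on the
regression slope from 1,000 case-resampling bootstraps under an explicit
seed. Complete-case analysis: subjects missing either variable are
dropped and counted (n_in = n_out + n_dropped). Analytes are analysed
independently with no multiplicity correction.

## Synthetic-data model

The generator's defaults are the study conditions the tests assume.

*Calcium sessions.* Sampling 10 Hz; 15-s tones; alternating NT/CS⁺ order
with 45-s inter-tone intervals (leaving the full 15-s pre-tone baseline
tone-free); i.i.d. Gaussian frame noise (SD 1). The tone-locked response
is a difference of exponentials (rise 0.5 s, decay 3 s) — the transient
shape is not critical, any smooth kernel supports the recovery tests —
normalized so its largest 1-s bin average is 1 and scaled so the planted
peak of the *single-trial* binned z equals `response_amplitude` (default
6); block-averaging B trials scales the expected peak by √B since the
signal is deterministic while baseline noise shrinks. Trial-to-trial
variability is a per-trial Gaussian gain (relative SD 0.2, clipped at 0)
— exposed as a parameter because no canonical value exists for PL
transient variability. Archetype counts are allocated deterministically
by largest remainder. Seeding is counter-based (`(seed, neuron_index)`
keys), so enlarging a population never reshuffles existing neurons. Slow
drift, photobleaching, motion and spike dynamics are deliberately absent:
the per-block baseline z-transform is invariant to them by construction,
so recovery tests exercise the classification contract, not artifact
robustness — passing tests say nothing about motion-corrupted real data.

*Photometry.* Native 100 Hz, baseline ≈ 100 a.u., a slow shared sinusoid
on both channels (isosbestic carries no transients), sensor noise SD 0.5.
Planted transient peak in downsampled pre-tone-z units is
`base_peak_z − freeze_slope_z · freezing/100` (defaults 8 and 4), an
explicitly decreasing function of trial freezing. The defaults keep
planted amplitudes above the ceiling of the peak statistic under pure
noise (the max over ~150 samples of a unit-variance z trace is ~2.5–3),
so the planted direction, not extreme-value noise, dominates the
high/low-pool comparison. Freezing frames are a deterministic leading
block within each tone, making per-tone freezing percentages exact.

*Human cohort.* n = 80 subjects by default. Log 2-AG is Gaussian (mean 2,
SD 0.5 log-units); per-subject generalization is
`0.3 + 0.5·(r·z_ecb + √(1−r²)·ε)` with planted r = 0.223 by default —
the correlation magnitude the pipeline's recovery tests target. Startle
trials realise the generalization as the CS⁻/CS⁺ recall gap in ITI-mean
units, under a per-subject lognormal gain (removed exactly by ITI
standardization) and trial noise SD 0.1. Trial noise attenuates the
recovered correlation by < 1% at these settings, well inside the ±0.05
recovery band the tests assert. Two eCB time points bracket the planted
level symmetrically (±5%) so their mean is exact.

Ground-truth labels are returned as separate objects and written only to
a dedicated `ground_truth.csv`, never into the data files the analysis
stages read.

## Problem sizes and calibration checks

The test suite runs planted-fraction recovery at 400 neurons × 10 seeds,
classifier-oracle equality on 10⁴ random traces, Ward-oracle equality on
50 random 12-neuron instances, preference-bound checks on 10⁵ random
inputs, KS null calibration on 1,000 replicate pairs (n = 200 each),
association type-I calibration on 1,000 null cohorts (n = 80), and human
parameter recovery over 200 seeds — sizes chosen so binomial/Monte-Carlo
error is comfortably below each asserted tolerance. `scripts/acceptance.py`
re-runs the same computations at the same sizes except the human recovery
(50 seeds, standard error of the mean r ≈ 0.01).

## Known limitations

- The synthetic generator omits drift, bleaching, motion and correlated
  noise; conclusions about robustness to those require real data.
- The asymptotic KS p-value is used throughout; at very small n the exact
  method would differ.
- The Mahalanobis distance with ≤ K reference bins is regularizer-scaled
  (see above); it supports within-study group contrasts, not absolute
  interpretation.
- The whole-session z-scalars use the first 2 presentations per type by
  convention; sessions with systematic within-session drift in
  responsiveness would need the presentation window parameter exposed on
  `ztransform_whole_session`.
- Cross-day neuron registration and any imaging-preprocessing steps
  (source extraction, motion correction) are out of scope; inputs are
  assumed to be extracted traces.
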