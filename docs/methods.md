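# Methods

This note documents the models, numerical choices and limitations of the
package, stage by stage. Notation: a cohort has subjects (children) `s`
belonging to one of three classes (healthy, transient wheeze, asthma),
each delivering several breath samples; a breathogram is a uniform
retention-time grid (minutes) with a total-ion-current (TIC) trace and one
stick mass spectrum per scan over integer m/z 35–350.

## Synthetic cohort model

The generator exists so the whole chain can be validated against a known
truth; it emulates the statistical structure of a longitudinal preschool
breath study, not the physics of a GC-tof-MS instrument.

**Abundances.** True abundance of compound `c` in sample `i` of subject
`s(i)` in class `k(i)`:

    log a_ic = log(base_c) + log(effect_k(i),c) + u_s(i),c + e_ic

with `u ~ N(0, subject_sd²)` shared by all of a subject's samples (the
"biological mean" of that child) and `e ~ N(0, sample_sd²)` per sample.
Defaults `subject_sd = 0.4`, `sample_sd = 0.3` on the natural-log scale —
between-subject variation larger than within-subject, the regime that
motivates per-subject centering and subject-grouped validation. Base
abundances are log-normal (a few compounds dominate the TIC, as in real
breath). Each non-discriminatory compound is absent from a sample with
probability 0.3 (genuine zeros; discriminatory compounds are always
present so that the planted signal is a magnitude effect, not a detection
effect).

**Effect structure.** Planted discriminatory VOCs are multiplicative on
abundance (additive in log). The default effect table mirrors the
two-binary-model design: `n_shared` compounds shifted in asthma only
(visible to both models), `n_healthy_model` compounds shifted equally in
both wheeze classes (an "inflammation" signature, visible only against
healthy), and `n_wheeze_model` compounds shifted in transient wheeze only
(visible only in the wheeze comparison). Each compound's direction is
random, and the signed asthma-vs-transient difference is recorded so
recovery can be scored. The package's "strong effect" profile is a log
shift of 1.5 (≈4.5-fold), i.e. 3.75 subject-SDs; the parameter-recovery
benchmark uses 1.0–1.5 subject-SDs.

**Raw signal.** The TIC is a sum of unit-area Gaussian peaks — apex at the
compound's retention time displaced by a smooth bounded warp (cubic spline
through 4 random knots, clipped at `max_rt_shift`), width drawn per
compound from 0.03–0.08 min — plus a smooth non-negative baseline (three
low-frequency cosines plus an injection-tail exponential, scaled to
`baseline_amplitude`) and Gaussian noise with sd
`noise_sd · (1 + 0.1·sqrt(TIC))` (heteroscedastic, detector-like). Because
peaks have unit area, the noiseless baseline-free TIC integrates exactly
to the summed abundances, which pins the whole integration chain. Per-scan
spectra are the abundance-weighted mixture of the contributing library
spectra; baseline and noise are applied to the TIC only. Retention shifts
are smooth splines, deliberately *not* piecewise linear, so COW can only
approximate them — a stress test, not a rigged match.

**What the generator does not model** (and what passing tests therefore do
not show): instrument drift between batches, sampling-bag and
sorption-tube chemistry, detector saturation, spectral noise,
retention-index nonlinearity between runs, and realistic peak densities.
The default library holds 80 compounds, far below the 300–500 peaks of a
real breathogram, because the integrator deliberately performs no
deconvolution of co-eluting peaks (a stated non-goal); at realistic
density the merge step would be dominated by co-elution artifacts that
this package does not claim to solve.

## Preprocessing

**Trim.** Scans outside [1.3, 23] min are discarded (noisy spectra at the
run start, column bleed at the end); boundaries inclusive, with a 1 ns
float tolerance on the grid.

**Wavelet denoising.** Daubechies-4 decomposition to level 2; detail
coefficients soft-thresholded at the per-level universal threshold
`σ·sqrt(2 log n)` with `σ` from the median absolute deviation. Hard
thresholding and plain truncation of the detail levels are available; the
default is pinned by tests, not by any external source.

**Baseline.** Asymmetric least squares on a Whittaker smoother:
minimize `Σ w_i (y_i − z_i)² + λ Σ (Δ² z_i)²` with `w_i = p` above the
baseline and `1 − p` below, iterated to weight stabilization. Defaults
λ = 1e8, p = 0.1. λ is a stiffness per grid point: 1e8 on a 0.02-min grid
yields a nearly linear baseline, appropriate for slow drift; tests that
plant faster sinusoidal drift use λ = 1e4 (matched to the drift's
frequency content) and a smaller p when peaks dominate the trace. Output
is clipped at zero.

**COW alignment.** The reference chromatogram is, by default, the sample
with maximal mean TIC correlation to all others (deterministic,
data-driven); it is cut into segments of 20 points (the last absorbs the
remainder, merged when it would be shorter than 2 points). Each interior
boundary of the target may shift by at most the slack (7) from its nominal
position, endpoints fixed; each target segment is linearly resampled onto
its reference segment. The objective is the summed segment Pearson
correlation **minus** two regularizers that plain COW lacks: reference
segments whose dynamic range is below 1e-3 of the signal's range score 1.0
regardless of the target (correlation is affine-invariant, so such
segments are pure noise amplifiers — without this rule a flat,
baseline-clipped target segment "gains" correlation by stretching into a
neighbouring peak tail), and every boundary pays 1e-4 per point of
deviation from nominal (breaks exact ties toward the identity warp).
Correlation differences from genuine misalignment are orders of magnitude
larger than both. The dynamic program over boundary positions is globally
optimal for this objective — verified against exhaustive enumeration on
60-point signals — and the spectra are carried through the same
piecewise-linear warp.

**Peak detection/integration.** Local maxima with prominence ≥5× the MAD
of the corrected TIC and width ≥3 scans; integration bounds at the
flanking minima, split at the lowest point between adjacent apices so
bounds never overlap; trapezoidal areas in minutes. The peak's consensus
spectrum is the intensity-weighted mean of the scans at ≥50% of apex
height: the apex region is far less contaminated by partially co-eluting
neighbours than the full integration window, and merging quality depends
directly on this choice.

**Outlier screen.** PCA on the TIC matrix; flag samples whose score
distance or orthogonal residual exceeds `threshold_sd` robust (MAD-based)
standard deviations. Flag-only: nothing is removed automatically.

## Feature building

Peaks merge into compounds greedily: samples in ascending id order, peaks
in ascending retention time; a peak joins the best-correlated existing
compound within 0.1 min of its consensus retention time if the spectral
correlation reaches 0.9, else founds a new compound. One peak per sample
per compound; on a clash the higher correlation wins and the displaced
peak founds its own compound. Consensus retention time is the mean apex,
the consensus spectrum the area-weighted mean. The agglomeration is
deterministic and order-invariant by construction.

Normalization is per-sample total area (rows sum to 1); probabilistic
quotient normalization (divide by the median quotient to the column-median
reference over shared nonzero support, after total-area normalization) is
available as a cross-check — on synthetic data the two give the same
class structure. The presence filter keeps a compound iff it is nonzero in
at least 20% (inclusive) of the samples of at least one class. Per-subject
centering subtracts each child's own mean per compound (a single-sample
subject becomes a zero row — documented degenerate case); it is used for
exploration only. The rank transform (column-wise, ascending, average
ties) feeds the dissimilarity model; ranking uses the normalized,
*uncentered* table because ranks of centered single-sample subjects are
degenerate.

## Random forests

Two binary problems: healthy vs asthma (deviant lung processes) and
transient wheeze vs asthma (asthma-specific signal); never one multiclass
forest — two binary models give directly interpretable importances.

The split is the Duplex algorithm on subject-level mean profiles within
each class: the two mutually farthest subjects seed the training set, the
next farthest pair the test set, then alternating max–min-distance
assignment until the test set holds 20% of the class's subjects (at least
one). All of a subject's samples follow it, so no child is ever split
across train and test.

Forests are 1000 CART trees (scikit-learn trees; √p features per split,
grown to purity), bagged with explicit bootstrap records. The bootstrap
unit is the sample (classical) or the subject — all of a drawn subject's
samples enter together — the latter accounting for cluster-correlated
repeated measurements; on synthetic data with the default within-subject
correlation both give comparable accuracies, and both are above chance
wherever effects are planted. Out-of-bag votes (trees whose bootstrap
excluded the sample, or its subject) give the internal error; permutation
importance permutes one variable among a tree's oob cases and averages the
accuracy drop over trees (a constant variable is exactly zero by
construction); proximity is the fraction of trees in which two samples
share a terminal node, computed for arbitrary sample sets so held-out
samples can be projected. Subject-level classification is the modal
predicted class over a subject's samples, exact ties reported as
"undefined" and excluded from the subject-accuracy denominator (counted
separately). ROC sweeps the unique vote fractions; the reported cutoff
maximizes Youden's J, ties resolved toward 0.5. The discriminatory VOC
panel is the union of the two models' top-12 importances (ties at rank 12
broken by variable id).

## Proximity projection

Each model's training proximity matrix is column-mean-centered and
eigendecomposed (via SVD); component signs are fixed by making each
component's largest-magnitude loading positive, so runs are reproducible.
Samples outside a model are dropped down its trees, their proximity vector
to the training samples centered with the training means and multiplied by
the loadings — training samples projected this way reproduce their own
scores to machine precision, and the map is affine in the proximity row.
The combined view takes score 1/score 2 from the transient-vs-asthma model
and score 3/score 4 from the healthy-vs-asthma model (score 4 is computed
and written but not plotted, mirroring the three-axis view); subsets
restrict to the inclusion visit (visit 1) or each subject's final visit.
PCA is performed on the proximity matrix directly, not on 1 − proximity
(configurable); with 2 PCs retained per model.

## d-PLS-DA

With the selected VOCs (default: the 17-member union), training samples
are rank-transformed; query samples are placed on the same scale by
linearly interpolating each variable's training value→rank map, clamped
outside the training range (training D is untouched by queries). The
dissimilarity matrix D holds Euclidean distances in rank space; the model
`y = Db + r` (y coded −1 for transient wheeze, +1 for asthma) is fit by
PLS1 with deflation on the column-centered system. At full rank the PLS
solution equals ordinary least squares (tested against the
normal-equations solution). Model complexity is chosen by leave-one-out
cross-validation in which the held-out sample is removed from *both* axes
of D — it is neither a training row nor a distance landmark — and the LV
count minimizing RMSECV wins, smaller counts on exact ties. Prediction is
`ŷ = (D_q − column means)·b + ȳ`, thresholded at the class-code midpoint
(0), exact boundary to the negative class. The pipeline applies the model
to inclusion-visit samples of the two wheeze classes only, training on the
Duplex training subjects and validating on the held-out subjects, with
both sample-level and subject-level accuracies reported. `max_lv` defaults
to min(n_train − 1, 15).

A note on the LV rule: on a noiseless, perfectly separable toy the LOO
curve decreases and flattens, so a strict argmin can sit at a large LV
count that is better by ~1e-4; the rule is kept strict (no parsimony
heuristic), and in practice — wherever there is any class overlap or
noise — the curve has an interior minimum at a small count (2 on the
default synthetic cohort).

## Pipeline, seeds, problem sizes

A single pydantic-validated config drives all stages (unknown keys and
out-of-range values are rejected before anything runs). One master seed is
fanned out to per-stage streams through `numpy.random.SeedSequence`; the
run manifest records SHA-256 digests of every stage output, and a rerun
with the same config is bit-identical.

Default problem sizes are scaled to desk use while preserving the study's
structure: 12/20/20 subjects with 3–5 samples each (≈210 breathograms),
an 80-compound library on a 0.02-min grid, 1000 trees per forest. The
statistical-calibration checks use a two-class null cohort of 18+18
subjects with 20 label permutations (chance reference: the permuted
cohort's majority-class sample rate — the realized test-set majority is
upward-biased at these test-set sizes); the recovery benchmark plants 20
discriminatory compounds (6 shared, 7 per single model) at 1.5 subject-SD
effects in a 60-subject cohort and requires ≥80% recall of the planted
set with all estimated signs correct.

## Known limitations

- No deconvolution of co-eluting peaks: compound recovery through the
  rendered-signal path loses peaks that overlap within the integrator's
  resolution (~70–80% recall of planted VOCs at default density, vs ≥90%
  at the abundance level).
- The COW model is piecewise linear and cannot exactly invert the
  generator's smooth warps (by design).
- The outlier screen is a standard PCA distance screen, not a robust-PCA
  estimator; it is flag-only.
- Proximity matrices are symmetric with unit diagonal and entries in
  [0, 1] but are not guaranteed positive semidefinite.
- Binary d-PLS-DA only; no sparse or multiclass variants.
- mzML files can be read (via pyteomics) but not written; CSV/TSV are the
  interchange formats.
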