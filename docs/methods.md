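# Methods

## Scope

`abequant` implements a semi-quantitative diagnostic pipeline for neonatal
acute bilirubin encephalopathy (ABE) on T1-weighted MRI, driven entirely by
synthetic phantom data: cohort generation, ROI quantification, ROC/Youden
threshold selection, diagnostic evaluation statistics, cohort covariate
tests, and a desk-scale residual-CNN classification protocol with class
activation mapping (CAM).

## Phantom cohort model

Each synthetic neonate belongs to one of two groups (ABE, the positive
class, or non-ABE hyperbilirubinemia) and carries

* **true normalized-intensity ratios** drawn from group-specific normals —
  defaults GP 1.39 ± 0.06 vs 1.33 ± 0.06 and STN 1.47 ± 0.09 vs 1.42 ± 0.07
  (mean ± SD); the ± values are treated as standard deviations, consistent
  with their use in two-sample t-tests at these sample sizes;
* **clinical covariates** (age in days, weight in kg, gestational age in
  weeks, total serum bilirubin in µmol/L, albumin in g/L, sex from a
  Bernoulli on the group male proportion), drawn from group normals and
  clamped to physiologic ranges (age to [1, 18] days — unbounded normal
  draws would otherwise produce impossible values);
* a BIND severity score (1–9 for ABE, mild scores more likely; 0
  otherwise), carried as metadata only.

Default group sizes are 47 ABE vs 32 non-ABE.

**Rendering.** A subject is an 18-slice axial stack of 128×128 grids. The
brain is an ellipse of white-matter-level tissue (`wm_mean`, default 100
arbitrary units). The three central slices carry the ROIs: an anterior
subcortical WM reference ellipse, and bilateral GP and STN ellipses pooled
into one mask code per structure (the score is a single per-patient value,
so laterality is not modelled). ROI geometry is expressed in grid fractions
and is invented; STN is placed inferior to GP with a small gap so that the
two structures remain separable at coarse CNN feature resolutions.
Rendering fails loudly if any ROI would occupy fewer than 20 pixels.

Regional mean intensity before noise is `wm_mean × true ratio` in GP/STN
and `wm_mean` elsewhere in the brain; voxel noise is independent zero-mean
Gaussian with SD = `noise_cv` × regional mean (default `noise_cv` = 0.02),
clipped at zero. The default keeps the measurement SD of an extracted ratio
well below the between-subject SD of 0.06.

**Variance separation.** Between-subject (biological) variation lives
exclusively in the cohort sampler; voxel noise lives exclusively in the
renderer. Extracted ratios therefore converge to the configured
subject-level distribution as `noise_cv → 0`, which is what the
parameter-recovery tests exercise. The ratio of ROI means is biased only at
second order in `noise_cv` (≈ `noise_cv²/n_WM` relative), negligible at the
default settings.

What the phantom does **not** emulate: real neuroanatomy, partial-volume
effects, bias fields, 3D acquisition physics, skull/CSF, registration
error, or rater behaviour. Passing tests demonstrate the correctness of the
analysis machinery under the stated statistical model, not clinical
performance on real scans.

## ROI quantification

For each subject the slice with the largest combined GP+STN pixel count is
selected (ties to the lowest slice index); the scores are

GP_norm = mean(GP)/mean(WM), STN_norm = mean(STN)/mean(WM)

computed on that single slice (no averaging across slices). Ratios are
exactly invariant under global intensity rescaling. Missing ROIs raise
errors rather than defaulting — silent fallbacks would corrupt the feature
table.

## ROC analysis and cutoff selection

The decision rule is `score ≥ threshold → ABE` (hyperintensity means higher
score means disease). Operating points are evaluated at the midpoints of
adjacent distinct scores plus one sentinel above the maximum and one below
the minimum, so every achievable confusion matrix is represented exactly
once and reported cutoffs follow the midpoint convention. AUC is the
trapezoidal area over (1 − specificity, sensitivity); it equals the
Mann-Whitney probability P(score⁺ > score⁻) + ½P(tie), and an independent
brute-force pair-counting oracle is shipped for verification. The Youden
cutoff maximizes J = sensitivity + specificity − 1, with ties broken toward
the smallest threshold (favoring sensitivity; the tie convention of
commercial statistics packages is not recoverable, so one was fixed).

For normal scores the closed-form AUC Φ((μ⁺ − μ⁻)/√(σ⁺² + σ⁻²)) serves as
the infinite-sample anchor: 0.7602 for the GP distributions and 0.6695 for
STN. Empirical AUC is an unbiased estimator of this quantity, so
Monte-Carlo means over replicate 47-vs-32 cohorts sit on the closed form to
within simulation error; the mean Youden cutoff for the equal-variance GP
case sits near the midpoint of the group means (1.36).

## Evaluation metrics

The confusion matrix takes ABE as positive. Metrics are kept at full
precision; the display convention renders sensitivity and specificity at
0.1% resolution zero-padded to two decimals (the resolution of ROC
coordinate listings) and precision, F1, accuracy and AUC at 0.01%. Zero
denominators surface as explicit `undefined` flags, never numeric
sentinels. Multi-run aggregation reports mean ± sample SD (n − 1).

Fleiss' kappa follows the standard formulation (per-subject agreement
P_i = (Σ_j n_ij² − r)/(r(r − 1)), chance agreement from pooled category
proportions) and is used for inter-rater agreement. Accuracy of two
classifiers is compared with a 2×2 Pearson chi-squared on correct/incorrect
counts, one degree of freedom, without continuity correction (the Yates
correction would not reproduce the reference comparison from the
reconstructed counts).

## Cohort statistics

Continuous covariates: two-sample t-test from summary statistics, Welch by
default with a pooled option (the original test flavor is unstated;
p-values from 2-decimal summaries can only be matched approximately
either way). Sex: 2×2 chi-squared. The normalized intensities support an
ANCOVA: ordinary least squares of the feature on intercept + group
indicator + covariates, the group term tested by a partial F (equal to the
squared t of the coefficient), with the adjusted group effect reported. PMA
(post-menstrual age) is emitted by the generator as gestational age plus
chronological age in weeks. Rank-deficient designs raise a collinearity
error.

## CNN protocol

The classification protocol mirrors a standard medical-imaging pipeline:
per-slice min-max normalization to [0, 1], resize to a square 3-channel
input, stratified 80/20 train/test split with five-fold cross-validation
inside the training set, augmentation applied in the fixed order rotation
(±30°) → vertical flip (p = 0.5) → zoom (0.9–1.1) → translation (±30 px)
with reflection padding, and SGD-with-momentum training (defaults: learning
rate 3 × 10⁻⁴, 6 epochs, minibatch 10, momentum 0.9). The default split
unit is the **subject** — slices of one neonate never straddle a split,
removing a leakage risk inherent to slice-level splitting — with a
slice-level mode available. Two to three central GP-covering slices per
subject feed the network.

The backbone is a small residual network written in numpy: 3×3
convolutions, residual blocks `y = F(x) + x` with F = conv–BN–ReLU–conv–BN,
stride-2 downsampling blocks that double the channel count and use
zero-padded identity shortcuts, then a ReLU, global average pooling, a
fully connected layer and a softmax over two classes. Batch normalization
is essential here: without it a from-scratch network of this size does not
train at any stable learning rate on these images. Because running BN
statistics lag the rapidly moving weights on small datasets, they are
recalibrated after training by one pass over the training set (exact
dataset moments). With a zero-initialized branch every residual block is
the exact identity map, an assertable contract. Depth is configurable
(stages and blocks per stage); parameter count grows strictly with either.

Desk-scale experiments (tests and the acceptance script) run this exact
code at 32–64 px inputs, 8 base channels, 2 stages, learning rate 0.01 and
up to 20 epochs: a from-scratch network needs more optimization steps than
a pretrained 18-layer backbone fine-tuned at 3 × 10⁻⁴, and the reduced
sizes keep a full cross-validation in CPU minutes. Late-training
instability (a momentum-amplified step occasionally flipping a converged
solution) motivated the conservative learning rate.

**Class activation maps.** The CAM of the predicted class is the
FC-weighted sum of the rectified final feature maps, upsampled to the input
grid and min-max scaled to [0, 1]. Upsampling maps feature pixel *o* of a
stride-*s* grid to input pixel *s·o* (the receptive-field center under 3×3
convolutions with padding 1) rather than cell-center interpolation, which
would shift the map by (s − 1)/2 pixels. A spatially constant raw map is
returned as all zeros.

**Localization experiment.** Phantoms are configured so the two classes
differ *only inside the GP*: bright (1.6) vs dark (0.6) GP under an
identical bright STN (1.8) in both groups, making per-slice min-max
normalization identical across classes and removing any global brightness
cue. After training, the CAM peak of each correctly classified held-out
slice is scored against the GP mask **at feature-grid resolution**: a hit
is a peak within one feature stride of the mask (the map is computed on a
stride-2 grid with ~10-pixel receptive fields, so sub-stride peak placement
is below its resolution). Known caveat: localization of the *negative*
class is init-dependent — absence of a bright-GP feature needs no localized
activation, so some training runs discriminate via diffuse global-pooling
channels and their non-ABE CAMs do not concentrate on the GP. The
acceptance script therefore pools the localization rate over independent
experiment replicates; mean heat inside vs outside the GP mask (≈0.85 vs
≈0.2 for disease-class maps) is the clearer signal that evidence
concentrates on the lesion.

Null-label control: training on label-shuffled slices stays at chance
accuracy within binomial error — the protocol cannot manufacture signal.

## Experiment sizes

Monte-Carlo ROC experiments use 10⁴ replicate cohorts; parameter recovery
uses 500 subjects per group at `noise_cv` 0.02; the CNN experiments use 30
subjects × 3 slices at 64 px (localization) and 24 px (null-label control).
These sizes give standard errors comfortably inside the tolerances asserted
in the test suite while keeping the full suite and the acceptance script in
the minutes range on a single CPU.

## Known limitations

* The phantom's uniform elliptical ROIs cannot probe segmentation or
  registration error; real GP hyperintensity may be spatially non-uniform.
* The visual-inspection arm of the emulated study design (per-rater image
  readings) is not reproducible from summary data; only its analysis
  machinery (kappa, metric aggregation, accuracy comparison) is
  implemented and tested on synthetic ratings.
* The CNN's absolute performance numbers on phantoms say nothing about
  performance on real T1 images; the protocol, not the score, is the
  deliverable.
* Reference cohort-table p-values are reproduced only approximately from
  rounded summaries; exactness is not claimed.
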