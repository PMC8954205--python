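# Methods

`limbicnet` re-creates, at desk scale, an experiment on how image
restoration and anatomical cropping affect a deep-learning classifier for
Alzheimer's disease (AD) on FDG-PET, together with the explainability of its
decisions.  Clinical PET of this kind is access-gated, so the package ships a
synthetic phantom generator whose outputs have the statistical structure the
analysis needs, and every other stage (restoration, cropping, CNN training,
cross-validated evaluation, class activation maps) operates on those
phantoms exactly as it would on real volumes.

## Degradation model and phantom cohorts

Stored images are modelled as `g = psf ⊗⊗ f + N`: the clean image `f` is
blurred slice-by-slice with a 2-D Gaussian point-spread function
`psf(m,n) ∝ exp(−(m²+n²)/2σ_b²)` and corrupted by additive zero-mean
Gaussian noise.  The PSF is 2-D because axial slices are reconstructed
independently in much of the source data; no sinogram-domain physics is
simulated.

The phantom generator (`limbicnet.phantoms`) draws:

* **Anatomy** — an ellipsoidal brain filling most of the field of view
  (semi-axes 0.86/0.90/0.82 of the half-dims, ≈33% of the volume, as in
  template-space PET), containing disjoint ellipsoidal subregions for the
  middle frontal gyrus, middle temporal gyrus, insula, hippocampus,
  amygdala, thalamus, putamen and caudate, each lateralized (`_l`/`_r`) and
  mirror-symmetric; remaining brain voxels are labelled cortex.  The same
  geometry rasterized at the phantom grid is the atlas used for cropping and
  activation-map summaries, so atlas and volumes are voxel-aligned by
  construction.
* **Uptake** — each region has a fixed baseline intensity (arbitrary
  units; deep gray ≈1.1–1.15, medial temporal ≈0.95, cortex 1.0) times a
  per-subject, per-region log-normal factor with 5% sd, so classes overlap
  and the classifier is never trivially perfect.  AD subjects have the mean
  of each region in the *effect map* multiplied by `1 − reduction`
  (regional hypometabolism).  Defaults: 0.20 hippocampus, 0.15 amygdala and
  middle temporal, ~0.1 elsewhere in limbic/frontal regions.
* **Acquisition** — a scanner profile (blur σ_b in voxels, noise sd as a
  fraction of mean in-brain intensity, axial slice count) drawn per subject
  from a weighted profile list, emulating multi-scanner variability in
  noise and slice thickness.  Negative intensities are clipped at zero and
  the axial extent is decimated to the profile's slice count by
  nearest-slice selection.  A Poisson counting-noise option exists behind
  `noise_model="poisson"`; additive Gaussian is the default because it is
  the operative degradation model above.

Cohort generation is bit-reproducible from a single integer seed.  Default
grid: 64×64×40 voxels at 2 mm — a desk-scale stand-in for template-space
91×109×91.

What the phantoms do **not** emulate: real anatomy (gyri, ventricles,
partial-volume mixtures), spatial-normalization residuals, attenuation or
scatter artifacts, or correlated (reconstruction-filtered) noise.  Passing
tests therefore show the *pipeline logic and algorithms* behave as claimed
under the stated statistical structure — not that the same effect sizes
would be measured on clinical data.

## Restoration

**TV-l1 deblurring** solves
`f* = argmin_f ‖psf ⊗⊗ f − g‖₁ + λ‖∇f‖₁` per axial slice (λ = 0.01 by
default).  The norms are l1 for both terms, matching the "TV-l1" family the
method belongs to.  Minimization uses half-quadratic splitting: auxiliary
variables for the residual and the forward-difference gradient are updated
by soft shrinkage, and the quadratic `f`-subproblem is solved exactly in
the Fourier domain.  The slice is mirror-padded (kernel half-width + 4) so
the periodic FFT solve does not wrap image content; the padding is cropped
afterwards.  The coupling weight β follows a geometric schedule (1 → ×2 per
outer iteration, capped at 256, 8 outer iterations).  After each outer
iteration the candidate is clipped to ≥0 and accepted only if the true
objective on the original domain did not increase; this monotone safeguard
makes the objective trace non-increasing by construction and guarantees the
output never scores worse than the observed slice.  PSF support is
`ceil(3σ_b)` with renormalization after truncation.

**MMWF denoising** applies the median modified Wiener filter
`b(n,m) = μ̄ + (σ_n²−γ²)/σ_n² · (Ω(n,m) − μ̄)` with a square window
(default 5×5, mirror padding), where μ̄ and σ_n² are the window median and
population variance and γ² is the mean of all local variances (a fixed γ²
is available).  When γ² > σ_n² the Wiener gain is clamped at zero, so the
output falls back to the local median; σ_n² = 0 also yields the median.
The vectorized implementation is tested against an explicit per-pixel loop.

The experiment matrix labels denoising conditions by window size (3×3,
5×5).  Whether that label should instead denote a noise-variance parameter
is ambiguous in the source material; both readings are representable via
`MMWFConfig`, and the window-size reading is used because the filter has no
Gaussian width and its reference description fixes a 5×5 window.

## Cropping

`limbic_crop_box` returns the tightest axial slab covering the union of the
requested regions (default: hippocampus, amygdala, thalamus, putamen) plus
a margin (default 2 slices), keeping the full in-plane extent — a
slices-of-interest crop.  The crop box travels with every downstream
product so activation maps are reported in whole-volume coordinates.
Because restoration is per-slice and cropping keeps the in-plane extent,
restore-then-crop and crop-then-restore are identical; the pipeline crops
first to avoid restoring discarded slices.  The middle temporal gyrus lies
inside the default slab and the middle frontal gyrus outside it, so
cropping concentrates (but does not fully preserve) the AD effect.

## Classifier

A 3-D residual CNN implemented in NumPy (forward and backward passes,
im2col convolutions, batch normalization, max pooling, Adam), so training
is exactly reproducible on CPU from the seed:

    7×7×7 conv, stride 2, pad 3 → BN → ReLU
    3×3×3 max-pool, stride 2, pad 1
    stage 1: 3×3×3 conv + BN, identity skip, ReLU
    stage 2: 3×3×3 conv stride 2 + BN, with 1×1×1 stride-2 conv+BN
             projection branch, ReLU
    global average pool → FC-128 → ReLU → FC-2 → softmax

With 64/128 channels this reproduces the reference shape trace for both the
whole-brain (128×128×79) and cropped (128×128×10) inputs; stage 2 must use
stride 2 (its printed shapes halve even though its stride is listed as 1).
Inputs are normalized per volume by the mean in-brain intensity, since
phantom units are arbitrary.  Training uses mini-batch cross-entropy with
Adam (β₁=0.9, β₂=0.999, ε=1e-8) plus an L2 penalty on weight matrices
(default 1e-4, the default of the optimizer implementation the original
recipe used); defaults are batch size 4, 20 epochs, learning rate 1e-4.
Weight init is fan-in-scaled normal, seed-controlled.  After the final
epoch the BN running statistics are replaced by exact population statistics
from one pass over the training set: at batch size 4 the exponential
running estimate is too noisy to match train-time behaviour, and the
recalibrated statistics make evaluation deterministic and batch-size
invariant.  Prediction ties break toward the control class.

## Evaluation

AD is the positive class.  Sensitivity, specificity, accuracy, F1 and MCC
are computed from the confusion matrix with every 0/0 defined as 0 (this
affects only degenerate predictors, e.g. MCC of an all-AD classifier).
Two protocols: a stratified 70/30 train/test split, and stratified 3-fold
cross-validation over the full cohort (the default — the relationship
between the two protocols in the source description is ambiguous, and CV
uses every subject for testing exactly once).  Aggregates are across-fold
mean ± sd (ddof = 1); reports label the protocol used.

## Activation maps

The network ends in GAP followed by two FC layers, so single-layer CAM does
not apply directly.  Default: collapse FC-128→FC-2 into an effective
per-channel weight by multiplying the weight matrices (ignoring the
intermediate ReLU) and sum the final-conv feature maps with the AD-class
weights; gradient-weighted CAM is available as an alternative
(`method="gradcam"`).  Maps are trilinearly upsampled to the network input
grid, averaged across subjects (each subject contributes the map from the
fold in which it was held out), embedded at the crop offset, and summarized
per atlas region.  Only positive weights count toward importance; the
**non-brain fraction** — the share of total positive weight outside the
brain mask — quantifies how much of the model's evidence for AD lies
outside the brain.  Signed maps are still exported.

## Desk-scale benchmark

The qualitative headline — deblurring (σ_b = 2) plus limbic cropping beats
a raw whole-brain model on MCC, and focuses its activation maps inside the
brain — is reproduced on a fixed benchmark cohort: 60 subjects (40
control / 20 AD, preserving the ~70/30 imbalance), 64×64×40 voxels, effect
0.25 on hippocampus + middle temporal gyrus, one scanner profile with
σ_b = 2 blur and 10% noise.  The benchmark model keeps the architecture but
at reduced width (8/16 channels, FC-32) with 15 epochs, learning rate
2e-3 and weight decay 1e-3, chosen so that stratified 3-fold CV over both
conditions completes in CPU minutes while the optimizer still escapes the
majority-class solution on the 40-subject training folds (the original
recipe performs ~780 updates; a 40-subject fold at the original settings
performs ~60, too few to leave the collapse basin).  Both comparisons are
asserted over 5 master seeds with a ≥4-of-5 majority.

## Numerical notes and limitations

* All randomness flows from one master seed via `numpy.random.SeedSequence`
  spawning; identical configurations are bit-reproducible on CPU.
* Convolution boundary handling is mirror padding everywhere except the
  FFT deblurring subproblem (periodic on the mirror-padded slice).
* The negative-gain clamp in the MMWF and the 0/0→0 metric convention are
  deliberate conventions, stated above, not fitted choices.
* `degrade` resamples slice count by nearest-slice decimation; the pipeline
  conforms volumes back to the atlas grid by trilinear interpolation, which
  slightly smooths thick-slice scanners' data — intended, as it mimics
  resampling in spatial normalization.
* Training at cohort sizes this small is noisy; the benchmark asserts a
  seed-majority ordering, not absolute metric values.  Absolute values from
  the original study are not reproducible here because its data, cohort
  size and compute scale are out of reach at desk scale.
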