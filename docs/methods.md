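# Methods

This note records the model, the simulation that stands in for multi-site
neonatal data, the numerical choices, and what the tests do and do not show.

## Harmonization model

Site harmonization is cast as unpaired image-to-image translation between
two domains (sites). Two generators and two critics are trained jointly:

* `G_A: site1 → site2`, judged by critic `D_A` against real site-2 images;
* `G_B: site2 → site1`, judged by `D_B` against real site-1 images.

Critics maximize the penalized Wasserstein objective
`E[D(real)] − E[D(fake)] − λ_gp·E[(‖∇ D(x̂)‖₂ − 1)²]` with `λ_gp = 10` and
x̂ drawn uniformly on the segment between a real and a generated sample
(paired by batch position; batches are reshuffled every iteration).
Generators minimize `−E[D(fake)] + λ·L_recon` with the symmetric L1 cycle
loss and `λ = 20`. The L1 loss is averaged **per element** so λ is
independent of slice resolution. Both directions' critics carry their own
gradient penalty; the dual architecture is symmetric.

### Networks

*Generators* are U-Nets: stride-2 5×5 (or 5×5×5) convolutions, LeakyReLU
(slope 0.2), batch normalization in the encoder and decoder, transposed
convolutions mirroring the encoder, and concatenation skip connections.
Default depth 3 with base width 16 (doubling per level) for 64×64 inputs;
input spatial sizes must be divisible by 2^depth. The output head is a
linear 3×3 convolution **added to the input** (a residual head) with
small-scale initialization: an untrained generator is then close to the
identity map. This suits harmonization — the target transform is a modest
correction of an already-valid metric map — and it removes a failure mode in
which early, uninformative adversarial gradients destroy image content
before the cycle loss can re-anchor it. Outputs are unbounded during
training; at inference FA is clipped to [0, 1] and out-of-mask voxels are
restored from the input.

*Critics* are fully convolutional patch (Markovian) discriminators without
any batch normalization: LeakyReLU after every convolution except the final
scoring layer, and the overall score is the mean of the spatial score map.
The default 2D layer plan is kernels (4,4,4,3) with strides (2,2,1,1) and
widths (16,32,64,1), whose analytic receptive field is exactly 30×30; the 3D
plan appends z-kernels (3,3,3,2) at z-stride 1 for 30×30×8. Construction
fails if a plan's stride/kernel arithmetic does not reproduce the requested
patch size, and an empirical gradient-support probe is available
(`nn.receptive_field`) and tested against the arithmetic.

### Training schedule

RMSProp (α = 0.99) for every network. Within each iteration the critics
take `critic_steps` updates before one joint generator update; in addition,
`critic_warmup` critic-only iterations precede all generator movement, so
the Wasserstein estimate is informative from the first generator step. The
critic learning rate (`learning_rate`, default 5e-5) deliberately exceeds
the generator rate (`gen_learning_rate`, default `learning_rate/4`): RMSProp
normalizes gradient magnitudes, so without this imbalance the generators
outrun the critics and the translation degrades before converging. Two
further stabilizers address the limit cycle inherent to Wasserstein critics
(whose input gradients do not shrink as the fake distribution approaches the
real one, so the generators overshoot until the critic re-adapts): learning
rates decay linearly over the second half of training (`lr_decay`), and
inference uses a Polyak (exponential moving) average of the generator
weights (`gen_ema_decay`), which sits at the center of the oscillation
rather than wherever the last update landed. Training runs a fixed epoch
budget with the full loss history recorded; a non-finite loss aborts with
the iteration index. Everything is reproducible from one seed
(single-threaded CPU arithmetic).

2D models pool masked slices of the configured orientation over all
subjects; slices with under 1% mask coverage are excluded from training
(`background_slice_policy`). 3D models consume whole volumes.

### Desk-scale problem sizes

The full training/evaluation loop in the test suite runs on 64×64×16
phantoms, 20 training + 10 held-out subjects per site, depth-3/base-16
generators on axial slices, batch 8, critic_steps 3 with 60 warm-up
iterations, critic lr 3e-4, generator lr 2e-5, generator EMA decay 0.995,
and a few hundred generator updates. These sizes are the package's reference configuration for
synthetic experiments; larger cohorts, 128×128 matrices, depth-4/base-32
generators and several hundred epochs are the intended configuration for
real data.

## The autodiff engine

The networks run on a reverse-mode automatic differentiation engine written
on NumPy (`harmonet.autodiff`). Convolutions form a closed primitive triple
(forward, input-gradient, weight-gradient) whose backward passes are
expressed within the triple, so gradients of gradients — required to
differentiate the gradient penalty with respect to critic weights — are
exact. Convolutions are evaluated channels-last as one matrix product per
kernel offset, which is the fastest arrangement NumPy offers at these sizes.
Batch normalization uses a fused first-order backward; nothing in the
package differentiates twice through it (critics contain no batch norm).

## Synthetic data: what it emulates

The phantom generator reproduces the statistical structure the method
assumes, not anatomy:

* **Template**: an ellipsoidal "white matter" with base FA ≈ 0.22 (± smooth
  spatial variation), containing parallel tract tubes (radius ≈ 2 voxels,
  along Y) with base FA raised by 0.12 — tracts are coherent structures
  brighter than surrounding WM. Outside the mask FA is 0.
* **Covariates** (defaults, chosen once for a term-neonate cohort scanned
  around 41 weeks postmenstrual age): ages uniform on 38.3–43.7 weeks; sex
  by deterministic proportion (male fraction 2/3, so n = 42 gives exactly
  28:14, shuffled by seed); age slope `beta_age = 0.006` FA/week and a male
  offset `beta_sex = 0.007` FA inside tract masks (an effect size of
  roughly |d| ≈ 0.3 on tract means); a per-subject global offset
  (SD 0.015 FA) and voxel noise (SD 0.01 FA) on the whole white matter.
* **Site effects**: seeded Gaussian white noise smoothed to
  `smoothness_mm` (default 12 mm) and normalized, yielding smooth fields.
  `multiplicative` has spatial mean `1 + magnitude`; `additive` has mean
  `0.25·magnitude` FA (0.25 being nominal WM FA, so `magnitude` reads as a
  fractional WM shift for every kind); `nonlinear` applies the power
  `1/(1+magnitude)`, raising FA values in (0,1); `mixed` combines half-size
  multiplicative and additive fields. The transform order is
  `clip((g·x + a)^γ + noise)` — gain/offset, then power, then noise — a
  declared simulation choice, as is the field family itself: no generative
  model of real scanner differences is claimed. Ground truth is attached to
  every transformed volume.

Passing tests on these phantoms show the pipeline can remove a smooth,
moderately nonlinear, spatially heterogeneous site bias while preserving
planted covariate effects. They do not show robustness to real-scanner
effects that the phantom lacks: anatomy-correlated distortions, registration
error, motion artifacts, or site-by-age interactions.

## Evaluation definitions

* **RMSE** is per subject against the *reference site's* voxel-wise group
  mean over the WM mask, summarized by the median — a re-interpretation
  (labeled as such in reports), since unpaired cohorts admit no
  subject-level ground truth.
* **Absolute error maps** are between per-site group means.
* **Cohen's d** uses the pooled n−1 SD; on tracts it is computed on
  per-subject tract-mean FA. Zero pooled SD with equal means gives d = 0 by
  rule, with unequal means it is an error.
* **Tract profiles**: tract voxels are projected on the tract's principal
  axis (or a supplied direction), the projected extent split into
  `n_levels` equal bins (100 for real-scale tracts; fewer on short phantom
  tubes — an empty bin is an error naming the bin), and the metric averaged
  per bin. Age correlations are per-location Pearson r across subjects,
  two-sided, α = 0.05; zero-variance locations are flagged and excluded.
* **Group test**: mass-univariate Welch t with max-statistic permutation
  FWER control (identity permutation included, so p ≥ 1/(B+1)), or
  Mann–Whitney with Benjamini–Hochberg FDR. This deliberately replaces
  skeleton-based TBSS; every result carries a "voxelwise (not TBSS)"
  provenance field. Cross-validated runs are combined by overlaying
  per-fold significance (union) with per-voxel minimum p.
* **Mann–Whitney U** uses exact enumeration for untied samples up to n = 20
  per group, tie-corrected normal approximation otherwise.

## ComBat details

Per-voxel location/scale model with covariates age (weeks) and sex. Fitting
follows the standard parametric empirical-Bayes formulation: voxel-wise
least squares; standardization by the grand mean (site-size-weighted) and
pooled residual variance; per-site `γ̂` (mean) and `δ̂²` (variance) of the
standardized data; normal and inverse-gamma moment priors across voxels;
iterative posterior updates to tolerance 1e-4 (max 100 iterations). With a
`reference_site`, standardization is anchored on the reference cohort
(its α, β, σ), the reference site passes through unchanged, and the target
site's γ/δ are directly interpretable on the standardized scale — this mode
matches the tool's harmonize-toward-a-reference protocol and is what the
parameter-recovery test uses. `delta` is stored as the multiplicative SD
factor (the square root of the variance parameter). Empirical Bayes can be
disabled for exact-recovery tests. Voxels with zero within-site variance or
zero pooled variance pass through unchanged and are reported. The
no-reference EB path is verified against Bioconductor `sva::ComBat` on an
identical matrix (agreement to ~1e-8; output clipping and degenerate-voxel
handling are this package's own rules and are bypassed in that comparison).

## Numerical and degenerate-input rules

* FA values marginally outside [0, 1] (interpolation artifacts) are clipped
  with a logged warning; values beyond 1.5× the range width are rejected.
* Voxel-scaling factors at voxels with zero target mean are set to 1 and
  reported. All harmonizers leave out-of-mask voxels untouched and clip FA
  outputs to [0, 1] with a logged count.
* Fold splits are per-site (each fold carries both sites — adversarial
  training needs both domains), seeded, sizes differing by at most 1.
* Harmonizers fit on training folds only; held-out subjects never influence
  the parameters they are evaluated with.

## Known limitations

* The translation is learned per site pair; a new site pair needs retraining.
* No skeletonization/TFCE: voxel-wise tests are less sensitive than TBSS
  near tract edges.
* The phantom's site-effect family (smooth gain/offset + power) may flatter
  methods that assume smoothness; the dual-GAN advantage over voxel scaling
  on *nonsmooth* effects is untested here.
* Batch normalization uses batch statistics during training; very small
  batch sizes (< 4) make training noticeably noisier.
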