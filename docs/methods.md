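# Methods

## Problem and model

The package addresses slice-level screening for early ischemia on
non-contrast head CT (NCCT). Within ~12 h of stroke onset an infarct is
usually not yet frankly hypodense; the attenuation change against
surrounding parenchyma is a few Hounsfield units at most, which is why
first-line NCCT reads are frequently negative and diffusion-weighted MRI
is the reference standard. The pipeline treats the problem as binary
image classification per axial slice, followed by a deliberately
sensitivity-first aggregation to the patient level: a subject is called
ischemic iff at least one slice is predicted ischemic (the *any-slice*
rule). Under this rule a single true-positive slice rescues a patient, and
a single false-positive slice misclassifies a normal subject — the
asymmetry wanted in a screening triage setting.

### Classifier

The classifier is a VGG16-style convolutional network with a customized
head. Backbone: the standard 13-convolution stack (3×3 kernels, five
max-pooled blocks, 64→512 channels). Head: `dense(1049) → batchnorm →
dropout(0.5) → dense(1049) → batchnorm → dropout(0.5) → dense(2)` with a
**per-unit sigmoid** output, trained with **categorical crossentropy**
against one-hot targets ([1,0] ischemic, [0,1] normal) under Adam. The
tuned hyper-parameters are fixed as defaults: learning rate 0.001, batch
size 8, 4 epochs of up to 1000 steps, dropout 0.5, learning-rate decay
0.01 (applied as lr/(1+decay·step)), ε = 1e-7, first-moment coefficient
0.9, and 1049 units in both head dense layers (the source description is
singular — "the number of neurons in the dense layer" — so both layers
share the value; a per-layer override is one constructor argument away).

Pairing a two-unit sigmoid with categorical crossentropy is unusual and
has a consequence worth documenting: after renormalization inside the loss
(outputs are scaled to sum to one, the standard framework behaviour), the
loss constrains only the *ratio* of the two activations. The raw ischemic
unit therefore carries no calibrated meaning — in practice it saturates
near 1 for all inputs early in training. The slice **score** exposed by
the package is consequently the renormalized ischemic probability
p_isch/(p_isch+p_norm); thresholding it at 0.5 (ties → ischemic) is
exactly the argmax decision the loss optimizes. A `softmax_output` switch
is provided for comparison.

Two further numerical choices keep the head healthy at desk scale:

- **Near-zero output initialization.** The final dense layer starts with
  weights scaled by 0.05 so both units begin near p = 0.5, avoiding an
  early saturation transient of the sigmoid output (a saturated unit
  receives vanishing gradient and takes epochs to recover).
- **BatchNorm re-estimation ("precise BN").** The head order
  dense→batchnorm→dropout means dropout noise inflates the batch moments
  each BatchNorm sees during training; exponential running averages then
  misrepresent the dropout-free inference distribution, which at small
  scale is enough to collapse eval-mode predictions. After every epoch the
  package replays up to 256 dropout-free training batches and installs the
  averaged batch moments as the inference statistics.

No deep-learning framework is used: the layers (Conv2D via im2col, Dense,
BatchNorm 1-D/2-D, MaxPool, Dropout, ReLU/Sigmoid), Adam, and manual
backpropagation live in `ncctscreen.nnet` (~300 lines of numpy). Gradients
are verified against central finite differences in the test suite, and
im2col/col2im against the adjoint identity. ImageNet-pretrained backbone
weights are not bundled; requesting them raises unless random
initialization is explicitly allowed. All experiments here run the
`small_cnn` backbone (3 conv blocks, 8→32 channels, same customized head)
at 64-px input — the structural contracts (two batch-norm layers after the
dense layers, 2-unit sigmoid output, the tuned hyper-parameter set) are
asserted on the full VGG16 build.

### Preprocessing chain

Order-enforced via stage tags: `windowed → skull_stripped → (noisy →
denoised) → cropped`.

- **Windowing.** g = round(255·(HU − (c − w/2))/w) clipped to [0,255],
  brain/sinus window c = 40 HU, w = 150 HU; rounding is half-up (the
  converting viewer's convention is unknown; half-up is fixed and
  documented for reproducibility). Bone saturates this window at 255.
- **Skull stripping** (four steps): binary threshold at 250 (default;
  bone-saturated pixels) → erosion (disc r=3) then opening (disc r=5) of
  the brain candidate, largest connected component kept → mask
  multiplication → zero every pixel < 10. The eroded brain rim is restored
  by dilating the selected component by the erosion radius; since
  (A⊖r)⊕r ⊆ A the bone cannot re-enter the mask. The source describes the
  steps but no parameter values; all are exposed in `SkullStripParams`.
- **Noise / PSNR.** Because the intrinsic scanner noise of an image is
  unknown, a known quantity of Gaussian noise (mean 0, variance 0.001 on
  the [0,1] scale) is added post-stripping and denoising quality is scored
  as PSNR = 10·log10(255²/MSE) against the pre-noise slice (MSE = 0 is
  flagged "identical" rather than coerced).
- **Denoisers.** Median (3×3), Gaussian (σ = 0.5; larger σ destroys more
  edge than noise on these images), bilateral, and a residual-learning
  convolutional denoiser ("DnCNN-style"): Conv+ReLU, (depth−2)×
  Conv+BatchNorm+ReLU, Conv→1, predicting the noise that is then
  subtracted. It is trained on clean/noisy phantom patch pairs (32-px
  patches biased toward ≥30% tissue content, fresh noise each step, MSE
  loss, Adam 2e-3 with decay 2e-3, 1200 steps, depth 4 × width 16 at desk
  scale); its final projection is initialized near zero so training starts
  from the identity denoiser, which removes a strong initialization-seed
  dependence of the converged quality. On 20 held-out phantom slices this
  configuration reaches ~40 dB versus ~35.4 dB for the median filter and
  ~31.3 dB unprocessed. The
  original study's PSNR values depend on its private images and are not
  reproduction targets.
- **Cropping.** The inclusive bounding box of all nonzero rows/columns;
  conservative (keeps every nonzero pixel) and idempotent.

### Cross-validation and augmentation

Slices are shuffled into k = 10 folds differing by ≤1 in size. In
iteration i, fold i is the test set, a fresh random 10% of the remainder
is the validation set (seed = base + i) for early stopping (patience 3
evaluations), and the rest trains a fresh model. Folding is *slice-wise*,
faithful to the derivation protocol it mirrors, even though slices of one
subject may then appear on both sides of a split across folds; subject-wise
grouping can be had by passing subject-prefixed slice ids to `make_folds`
and grouping externally. Metric summaries are mean ± sample SD over folds;
AUC/AP are recorded as undefined (not 0) on single-class test folds and
excluded from the mean with a warning. Augmentation applies, per training
batch: intensity rescale to [0,1], a uniform intensity shift within ±8
gray levels ("channel shift" on a single channel), horizontal flip with
probability ½, rotation within ±3°, and zoom in [0.7, 1.0] (shrinking onto
a zero canvas, matching the black CT background). Random hyper-parameter
search draws seeded configurations and selects lexicographically: smallest
mean validation loss, ties broken by highest mean accuracy.

### Metrics

All eight ratio metrics use the printed formulas (ischemic = positive).
Zero-denominator metrics are surfaced as `None` so fold averages stay
honest. AUC is the tie-aware concordance probability (equivalently the
trapezoidal ROC area), AP the step-function sum Σ(Rₙ−Rₙ₋₁)Pₙ; both are
cross-checked against scikit-learn in the tests but implemented
independently.

## The phantom generator

The phantom emulates the geometry that the preprocessing steps care about,
not anatomy: a calvarial ring at ~1000 HU (thickness 14 px at 512),
parenchyma at 35 ± 1.5 HU texture, two paramedian CSF ventricle ellipses
at ~6 HU, an optional thin anterior falx calcification line at 300 HU, an
optional elliptical hypodense lesion whose profile is Gaussian-smoothed
(σ = 1 px) so its edge is subtle, and additive Gaussian scanner noise
(default SD 2 HU). Default lesion contrast is −8 HU — deliberately in the
barely-visible range; nothing quantitative is published about early-ischemia
contrast on NCCT, so the value is a configurable package choice. Cohorts
default to 25–40 slices per subject, ~60% of an ischemic subject's slices
carrying a lesion (the proportion implied by the derivation pool's
1631 : 476 split of ischemic-patient slices), and a 69 : 31 onset mix
(≤6 h : 6–12 h, the recruited 377 : 169). Learning-sanity experiments use
an *easy* variant (−40 HU lesions, radii 8–20% of the brain radius) so
that a CPU-scale model must succeed if the machinery is correct.

What the phantoms do **not** model: real skull geometry and partial-volume
bone edges, beam hardening and streak artifacts, gyral/sulcal texture,
old infarcts and leukoaraiosis mimics, 3-D continuity across slices.
Passing tests therefore certify the pipeline's mechanics (masking,
conservation, leakage-free folding, learnability of a known signal), not
clinical performance. The published clinical numbers enter only as exact
recomputation fixtures from their printed confusion counts — the private
training data and GPU-scale trained weights are explicitly out of scope.

## Problem sizes and determinism

Tests and the acceptance script run 128-px phantoms (512-px for the
skull-strip contract), ~300-slice cohorts, 64-px model inputs, 4-epoch
trainings and a 1200-step denoiser — sizes chosen so the whole suite runs
on a single CPU in minutes. Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); identical seeds give bit-identical
phantoms and training runs. Known limitations: the desk-scale model's
subject-level accuracy on phantoms is capped by the any-slice rule's
sensitivity to single false-positive slices (a ~3% slice FP rate across
30+ slices flags most normal subjects); the slice-wise CV protocol permits
within-subject leakage by design; and the sigmoid/crossentropy head relies
on the renormalized score for calibrated decisions, as discussed above.
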