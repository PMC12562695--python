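# Methods

`gaseg` implements an end-to-end pipeline for automated en face
quantification of geographic atrophy (GA) from macular OCT volumes: a
synthetic data generator that reproduces the imaging phenotype of complete
RPE and outer-retinal atrophy (cRORA), a 3D-encoder/2D-decoder attention
U-Net, its training recipe, and the agreement analysis used to validate such
a model against manual grading. This note records the model, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The segmentation model

GA is a property of the *en face* retinal plane — a lesion footprint in
(lateral, B-scan) coordinates — but its diagnostic evidence is axial: loss
of the RPE band and hypertransmission of signal into the choroid beneath it.
The architecture therefore encodes in 3D and decodes in 2D:

* **Encoder** — `levels` stages of residual double-convolution blocks
  (3x3x3 kernels, leaky ReLU with slope 0.1 so no unit can die at the
  narrow widths used here, identity shortcut with a 1x1x1 projection on
  channel change), each followed by 2x average pooling in (z, x, y). The axial
  dimension stops being pooled once it reaches 1 (or becomes odd). Channel
  widths double per level from `base_channels`.
* **Axial collapse** — the skip connections drop the axial dimension: a
  1x1x1 convolution produces per-voxel logits that are softmaxed *over z*,
  the features are reduced by the attention-weighted sum, and a 1x1
  convolution mixes channels. The logit convolution is zero-initialized, so
  an untrained collapse is exactly the mean over z; training can sharpen it
  onto the depth range where atrophy is imaged. With `use_attention=False`
  the collapse is a plain mean (ablation).
* **2D decoder** — from the collapsed bottleneck upward: nearest-neighbour
  2x upsampling in (x, y), an additive attention gate on the collapsed skip
  (`alpha = sigmoid(psi(relu(Wg g + Ws s)))`, per-pixel `alpha` in [0, 1]),
  concatenation, and a residual 2D double-convolution block.
* **Head** — 1x1 convolution to one channel and a logistic squashing;
  output is a per-pixel GA probability on the (x, y) grid of the input.

An optional near-infrared reflectance (nIR) image may enter as a second
channel. nIR is natively en face, so it is injected at the finest 2D decoder
level rather than broadcast along z into the 3D encoder; `in_channels=2`
enables the path.

Input geometry follows the two clinical acquisition protocols: Spectralis
volumes (49 B-scans of 512x496 px) are subsampled to (z, x, y) =
(128, 128, 64) with a (128, 64) output mask; Cirrus volumes (200 B-scans of
200x1024 px) to (128, 128, 128) with a (128, 128) mask. Output masks are
binarized at probability 0.5, with ties mapping to lesion so the rule is
bit-exact testable.

The exact channel widths, level count and attention internals of such
architectures are design choices rather than published constants; the
defaults here (4 levels, 16 base channels, additive gates, softmax axial
attention) are declared in `NetConfig` and exercised by ablation switches.

## Training recipe

The loss is an equally weighted sum of pixel-wise binary cross-entropy
(computed from logits for stability) and soft Dice loss
`1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)` with `eps = 1e-6`,
averaged per sample over the batch. Optimization uses AdamW (decoupled
weight decay 1e-2 applied to convolution weights only) at a constant
learning rate, with global gradient-norm clipping (default 5) guarding the
occasional divergent trajectory at aggressive rates. Clinical-scale
defaults are 450 epochs, batch 32, patience 70, learning rate 5e-5;
patience counts *epochs* without improvement of the validation mean Dice,
and the returned parameters are those of the best validation epoch. The
output layer's bias is initialized at the foreground-prior logit (-2,
matching the ~10-15 % GA coverage of a typical field), which markedly
shortens the all-background phase at the start of training; short-budget
runs otherwise risk spending most of their epochs there.

Subject grouping is enforced at every data boundary: repeat scans of one
subject are highly correlated, so folds and the train/validation split are
dealt at subject granularity (subjects shuffled by seed, ordered by
descending scan count, dealt round-robin to balance scans per fold). The
cross-validation driver predicts each included scan exactly once, by the
model of the fold that held it out.

Because no deep-learning framework is part of the runtime, the network and
optimizer run on a small define-by-run reverse-mode autodiff engine written
on NumPy, with the 3D convolutions executed by numba-compiled kernels at
full-resolution stages and by BLAS matmuls over guarded shifted views of the
padded volume at the deeper, cache-resident stages. Gradients of every
primitive are verified against numeric differentiation and the convolutions
against `scipy.ndimage` in the test suite.

## Synthetic cohorts

Clinical GA cohorts cannot be redistributed, so validation runs on synthetic
volumes built from the cRORA phenotype:

* **Background** — dark vitreous; three bright bands (inner retina,
  ellipsoid zone, RPE) as Gaussian profiles in depth whose positions vary
  smoothly across the en face plane (low-order cosine fields); a dim
  exponentially decaying choroid under the RPE. The RPE is the brightest
  band by construction.
* **Lesions** — unions of 0-4 deformed ellipses (low-order angular
  harmonics, area within a few percent of the drawn equivalent radius's
  circle), with per-focus radius 0.4-1.2 mm inside a 6x6 mm field of view.
* **Atrophy imprint** — inside the lesion footprint the RPE band is
  attenuated by 80 % and everything below it amplified 2.5x
  (hypertransmission). The transition feathers over ~2 px *inside* the
  boundary; outside columns are bit-identical to the background, which makes
  identity and locality properties exactly testable.
* **Growth** — visit v's lesion is visit v-1's plus the k nearest outside
  pixels by Euclidean distance in mm, with k set by a programmed growth rate
  (0.5 mm^2/visit by default). This is isotropic dilation calibrated by
  area, not a biophysical model: it exists to exercise the longitudinal
  area-vs-visit readout, and guarantees monotone growth to the pixel.
* **Confounders** — eyes flagged as neovascular AMD receive 1-3 dark fluid
  pockets and 0-2 bright subretinal patches at loci outside the GA
  footprint; the GA ground truth is never modified.
* **Noise** — multiplicative log-normal speckle with unit mean
  (sigma = 0.2 in the study configuration).

Cohort defaults describe the study design used throughout the tests: 20
subjects, one eye, three visits, 30 % nAMD-confounded eyes, quality scores
drawn uniformly from [25, 45] so the device inclusion thresholds (>= 25 for
Spectralis-like, >= 5 for Cirrus-like scans) act on plausible values. Sizes
the generator does not inherit from a protocol (lesion radii, growth rate,
speckle level, confounder counts) were chosen once as clinically plausible
magnitudes and are ordinary parameters of `SyntheticParams`.

Two reduced device profiles (`spectralis_small`, `cirrus_small`) keep the
clinical field of view and phenotype at half the network resolution
((64, 64, 32) input, (64, 32) mask); all train/evaluate experiments in the
test suite and the acceptance script use them so a complete 5-fold
cross-validation runs in minutes on one CPU. The same code paths run the
full-resolution profiles unchanged.

## What the baseline shows

`SlabThresholdSegmenter` is the classical non-learned readout: mean
intensity of the slab just below the RPE, thresholded (Otsu, guarded by a
minimum contrast over the median so a lesion-free projection is not split).
The RPE plane is a brightness-weighted cubic polynomial surface fitted to
the per-column argmax — necessary because inside a lesion the brightest band
is no longer the RPE. On noise-free phantoms the baseline reaches DSC
~0.9, which establishes that the synthetic task is well-posed (the label is
recoverable from the stated phenotype); under speckle and confounders it
degrades substantially, which is the margin the trained network is expected
to close.

## Numerical and statistical choices

* **Mask resampling** (native -> output grid) computes each target cell's
  exact source coverage by separable area weighting, then keeps the k
  highest-coverage cells with k the rounded total coverage. A fixed 0.5
  coverage threshold systematically inflates lesions when one axis is
  upsampled (the 49-B-scan axis onto 64 output pixels); rank selection
  conserves lesion area to within one target pixel by construction and the
  full field of view exactly.
* **Intensity normalization** is a per-volume z-score (constant volumes map
  to zeros), making the network invariant to device gain.
* **Dice of two empty masks** is defined as 1 (perfect agreement on
  absence); the convention only matters for synthetic edge cases.
* **Areas** are computed at the output-mask resolution (pixel count times
  pixel area); Bland-Altman differences are manual minus automated, limits
  of agreement at 1.96 sample standard deviations.
* **Strata comparison**: pooled-variance Student t-test for per-scan Dice
  between GA-only and GA+nAMD scans; equality of the two strata's area
  correlations via Fisher's z transform for independent correlations. No
  multiple-testing correction; alpha = 0.05. Degenerate guards (zero
  pooled variance, |r| = 1, tiny strata) return the documented conventions
  or typed errors rather than NaNs.
* **Connected components** for the multifocal coalescence diagnostic use
  8-connectivity.

## Scaled-down study replication

The end-to-end experiment in `tests/test_acceptance.py` and
`scripts/acceptance.py` mirrors the full design at desk scale: generate the
20-subject cohort, run subject-grouped 5-fold cross-validation of the
reduced network (3 levels, 8 base channels, (64, 64, 32) input) for 15
epochs per fold (patience 15, AdamW at 2e-3 with clipping, batch 4, 30 %
validation split), and aggregate per-scan Dice and areas. Under these
conditions the cross-validated mean Dice is ~0.9-0.95 and the
manual-vs-automated area r^2 is ~0.97-0.99, with stratified statistics and
Bland-Altman limits reported alongside. Stochastic checks are judged on
the median over three seeds; the seeds run lazily and stop once the
median's verdict is mathematically decided.

## Limitations

The phantom captures the geometry and contrast of cRORA but not real OCT
physics: no point-spread function, no vessel shadows, no motion artifacts,
no drusen or incomplete-RORA precursors, and speckle is i.i.d. log-normal
rather than correlated. Consequently the synthetic scores say the pipeline
is *correct and learnable end to end* — subject grouping, losses, early
stopping, statistics — but do not predict clinical accuracy; absolute DSC
and r^2 on real cohorts will be lower and device-dependent. Training is
single-device by design; multi-GPU execution, learning-rate schedules and
augmentation are out of scope.
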