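# Methods

## Problem and model

Fluorescent staining of cell structures is invasive, phototoxic and
labour-intensive. `virtustain` implements the label-free alternative for
adipocyte imaging: a conditional generative adversarial network (cGAN)
translates a z-stack of bright-field images of one field of view into three
virtually stained fluorescence channels — lipid droplets, cytoplasm and
nuclei — which are then quantified exactly as chemically stained images
would be.

The generator G is a U-Net-shaped fully convolutional encoder–decoder with
skip connections that maps a (C_in, H, W) bright-field stack (C_in = 7
defocus slices by default) to a (3, H, W) image bounded to [0, 1] by a
final sigmoid. The discriminator D is a conditional patch classifier: it
sees the bright-field stack concatenated with a candidate fluorescence
image and emits a logit map of size (H / 2^depth, W / 2^depth), each logit
judging one receptive-field patch. Training alternates

  l_disc = BCE(D(x, y), real) + BCE(D(x, G(x)), fake)
  l_gen  = adv_weight · BCE(D(x, G(x)), real) + λ · ‖G(x) − y‖₁

with the non-saturating BCE convention. A perfectly confused discriminator
(probability 0.5 everywhere) sits at l_disc = 2 ln 2, the adversarial
equilibrium. With adv_weight = 0 the objective degenerates to plain L1
regression, whose per-pixel optimum is the conditional median; the MSE
U-Net baseline (one single-channel network per stain, same training
configuration) has the conditional mean as its optimum. On one-to-many
mappings this difference is observable: the U-Net converges to the mean of
the possible targets, the cGAN to one of them. This mode-matching is the
mechanism that lets the cGAN draw plausible nuclei even though nuclei are
refractive-index-matched to the cytoplasm and hence invisible in
bright-field: the network infers them from surrounding context.

### Architecture and optimisation choices

Published architectural details for this workflow are not fully specified,
so the layer-level design here is the package's own:

* Generator: depth 4, base width 32 by default (desk-scale experiments use
  depth 3, width 12); widths double per level, capped at 8× base; one
  3×3 convolution + instance norm + leaky ReLU (0.2) per scale; nearest-
  neighbour upsampling + convolution in the decoder; sigmoid output.
* Discriminator: stride-2 3×3 convolutions (depth of them), instance norm
  after all but the first, final 3×3 convolution to one logit channel.
* Adam with lr 2e-4, β₁ = 0.5, β₂ = 0.999; λ = 100, adv_weight = 1;
  batches of 8 random crops (crop size divisible by 2^depth) with 90°
  rotations and flips as the only augmentation — geometry-preserving so
  intensity-based downstream features are not corrupted.
* Checkpoint selection: lowest mean validation nMAE_px across channels,
  evaluated at epoch 1, every `val_freq` epochs, and the final epoch.
* All convolutions use **symmetric padding**. This makes constant fields
  propagate exactly (a flat input yields a flat output) and, together with
  the trimmed, feathered tile blending in `predict`, makes tiled inference
  reproduce whole-field inference exactly for normalisation-free models.
  Instance normalisation computes field-global statistics, so with it
  tiled and whole-field outputs agree only approximately; the stitching
  invariant is therefore stated (and tested) for the purely convolutional
  path.
* The network stack is a compact numpy implementation (im2col + GEMM
  convolutions with hand-written backward passes, gradient-checked
  numerically in the test suite) sized for single-CPU desk-scale training.

## Intensity and I/O conventions

Images are 16-bit, range [0, 65535]; all computation happens after
division by the fixed constant 65535 (never per-image min–max), so stored
65535 maps to exactly 1.0 and intensity features are comparable across
images. TIFF page order: bright-field slices in acquisition z-order;
fluorescence channels ordered droplets, cytoplasm, nuclei. The nMAE_px
definition (below) is invariant to this joint rescaling, so it reads
identically on raw and normalised data.

## Metrics

* **nMAE_px** = mean(|pred − target|) / mean(target). The target-mean
  normaliser is the only common convention consistent with the published
  benchmark table this package ships for its consistency check: the
  printed MAE and target cells reproduce the printed percentages
  (150/1300 → 12%, 59/320 → 18%, 92/290 → 32%, 1600/6600 → 24%) under
  this definition.
* **SSIM** with the canonical constants: Gaussian window σ = 1.5
  (11 px support), K₁ = 0.01, K₂ = 0.03, declared dynamic range; a margin
  of half the window is cropped before averaging. Verified against an
  independent reference implementation to 1e-6.
* **PSNR** = 20 log₁₀(MAX) − 10 log₁₀(MSE) in dB, MAX = 1 on normalised
  images; identical images report +inf.

Set-level aggregation is mean ± population standard deviation per channel
(a single pair reports std 0).

## Profiling pipeline

Nuclei are segmented first: window-local Otsu thresholding (default window
64 px — nuclear intensity varies across a field), hole filling, and
shape declumping (watershed on the Euclidean distance transform seeded at
its maxima, minimum seed separation half the minimum expected diameter).
Window-local thresholds are bounded to [0.7, 1.5]× the global Otsu split
so foreground-free windows cannot threshold their own noise floor.
Cytoplasm is segmented as secondary objects: seeded watershed propagation
from the nuclei into an adaptively thresholded foreground with a larger
window (200 px) and a relaxed threshold correction (0.7, compensating the
uneven dye texture); each cell inherits its nucleus label, so
count(cytoplasm) = count(nuclei) identically. Lipid droplets are segmented
independently in two global-threshold passes targeting the small and large
size populations, declumped by intensity (h-maxima-seeded watershed on the
smoothed channel, prominence 0.15 of the foreground range — droplets are
uniformly round, so touching droplets split at intensity valleys, not
necks); the merge keeps large-pass objects and adds small-pass objects
whose overlap with them is at most 50%.

Features per structure class: count, mean area (px), integrated intensity,
mean of per-object mean intensities, and the standard deviation of those
per-object means. The std is taken **across objects** of per-object means
(population convention); the alternative reading — mean across objects of
within-object std — is not used. Intensities are measured on
[0, 1]-rescaled images. Empty label maps report count 0 and NaN features.

## Statistics

nMAE_cp is computed per image (|pred − target| / target, zero targets
excluded with a warning) and aggregated as mean ± sample (n−1) std in
percent; the ratio-of-aggregates form is reported alongside as a
diagnostic. Pearson ρ carries a Fisher-z 95% CI; group comparisons use
the two-tailed unpaired Student t test (equal variances, not Welch) with
stars ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001. The
diagnostic signature the report is built around: a systematic
(e.g., multiplicative) prediction bias yields high ρ with nonzero
nMAE_cp, which is what licenses comparative studies on virtual stains
even where absolute values deviate.

Calibration is verified by Monte-Carlo: the t-test type-I rate at the
0.05 level and the Fisher-z CI coverage at n = 15, ρ = 0.8 are each
estimated from 4000 simulations — enough that the simulation noise
(binomial σ ≈ 0.003) is small against the acceptance bands
[0.04, 0.06] and [0.93, 0.97].

## Synthetic phantom

The phantom emulates the statistical structure of paired adipocyte data:

* **Geometry.** Cells with an elliptical nucleus (mean radius 12 px,
  aspect jitter ±25%), a smooth cytoplasm blob (harmonic radial
  perturbation of a 48 px base radius) strictly containing the nucleus,
  and lipid droplets from two log-normal size populations (radius medians
  4 px and 15 px, log-σ 0.25/0.2, 20% large) — two populations because the
  droplet segmentation is built to target small and large droplets
  separately. Nucleus centres are rejection-sampled with pairwise
  separation of at least one mean nucleus diameter; droplet centres never
  fall inside an existing droplet so every ground-truth label stays
  visible. Default field 256×256 px, 6 cells, 25 droplets per cell.
* **Fluorescence.** Channel levels 22000 / 9000 / 15000 counts over an
  800-count background; droplets carry a quadratic radial fall-off (0.3)
  and an off-centre interior dip (strength 0.2) emulating the darker areas
  seen inside real droplets; the cytoplasm is multiplied by a low-pass
  (8 px) seeded noise texture (roughness 0.4) emulating the uneven,
  irreproducible dye reaction that no predictor can reproduce. Noise is
  additive Gaussian (σ 300 counts, optionally per-channel) plus a
  Poisson-like signal-dependent term (gain 0.05).
* **Bright-field.** 7 slices, background 30000 counts. The contrast
  hierarchy is the essential feature: droplets at weight 6000 with a
  defocus-signed central lobe (polarity flips across the focal plane), a
  defocus-dependent ring and an in-focus dark rim; cytoplasm a faint
  uniform darkening (1500); nuclei weight 0 — interiors statistically
  indistinguishable from surrounding cytoplasm. Slices are blurred with
  defocus-growing σ and carry additive read noise (σ 300).
* The defocus model is a cheap slice-indexed ring profile, not a physical
  optics computation; it provides monotone-in-defocus axial information,
  which is all the learning task needs.

All outputs are bit-reproducible given the parameter seed.

Desk-scale presets: the smoke experiments use 64×64 fields (1 cell,
12 droplets, radius medians 2.5 / 7 px — the full-scale geometry shrunk
with the field) with matched segmentation parameters
(`desk_phantom_params`, `desk_profiling_config`).

### What the phantom does not emulate

Real point-spread functions and diffraction, stain spectra, 3-D confocal
sectioning, focal drift, uneven illumination, cell debris and imaging
artefacts, biological variability of droplet/nucleus morphology beyond the
stated distributions. Tests passing on the phantom demonstrate that the
implementation is correct and that the method behaves as designed under
the stated contrast hierarchy and information asymmetry; they do not
demonstrate real-data accuracy, which depends on acquisition details the
phantom deliberately abstracts away.

## Problem sizes of the shipped experiments

Chosen as the package's desk-scale working points: segmentation recovery
over 50 seeded 256-px fields with noise at 10% of each structure's
contrast and non-overlapping objects; adversarial smoke training on 200
paired 64-px fields for 200 epochs (generator depth 3, width 12, 32-px
crops, batch 8) with 15 validation fields; the one-to-many toy mapping at
16 px with 400 (MSE) / 500 (adversarial) epochs. The acceptance script
runs a 120-pair / 120-epoch variant of the smoke experiment plus 25
recovery fields to keep a full reproduction within a few CPU-minutes.

## Known limitations

* Instance normalisation breaks exact whole-field/tiled equivalence (see
  above); the discrepancy is small but nonzero.
* Window-local Otsu assumes a bimodal histogram per window; the [0.7,
  1.5]× global bounds make it degrade gracefully, not optimally, on
  foreground-free windows.
* Adversarial training at desk scale is deliberately small; the smoke
  criteria are trend checks (improvement, structural similarity), not
  absolute reproduction of published real-data scores, which would
  require the real multi-magnification dataset and far longer training.
* The numpy network stack trains only on CPU and single-threaded BLAS;
  it is not intended for fields beyond a few hundred pixels at training
  time (prediction on large fields is handled by tiling).
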