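# Methods

## Problem and model

The package segments atherosclerotic plaque (foreground) against
everything else (background) in 2-D longitudinal B-mode carotid
ultrasound. The segmentation network, HRU-Net, is an encoder–decoder
with three ingredients chosen for small noisy datasets:

1. **ResNet-50 encoder with channel reduction.** The stock trunk (7×7/2
   stem, 3×3/2 max-pool, bottleneck stages of 3/4/6/3 blocks) emits
   features at H/2…H/32 with 64/256/512/1024/2048 channels. Each
   output is compressed by a 1×1 conv + BN + ReLU to 32/64/96/128/128
   channels. The reductions feed the skip connections and the decoder
   input only; the trunk itself is stock, so ImageNet-shaped weights
   load directly. Grayscale input is replicated to three channels
   before the stem for the same reason.
2. **Hybrid atrous convolutions.** A HAC block runs one 3×3 conv + BN +
   ReLU branch per parallel dilation rate (1, 2, 3, 5) plus one
   cascaded chain at rates 1→2→3 (receptive field 13×13 by
   RF = 1 + Σ r(K−1)), concatenates the branch outputs and fuses them
   with a 1×1 conv + BN + ReLU back to the input channel count. The
   block is channel- and resolution-preserving, so it can be dropped in
   at any pyramid level; the default placement is the three deepest
   levels (res4, res3, res2), and the ablation harness extends the
   placement deepest-first through res1, the stem feature, and the
   full-resolution decoder stage. An empty placement recovers the
   plain RU-Net baseline.
3. **U-Net-style decoder.** Each stage upsamples 2× (separable bilinear,
   half-pixel convention with edge clamp; the backward pass is the
   exact adjoint), concatenates the reduced skip feature, and applies
   two 3×3 conv + BN + ReLU. Stage widths mirror the reduced encoder
   widths (128, 96, 64, 32); a final upsample, two 3×3 convs and a 1×1
   head produce two-class logits, softmaxed per pixel.

The branch wiring inside the HAC block (per-branch BN/ReLU,
concatenation + 1×1 fusion, no weight sharing between cascade and
parallel branches) is this package's design choice: channel
preservation is what makes the placement sweep well-defined at every
level.

## Training protocol

Loss is the class-weighted Dice loss
`L = Σₑ Cₑ (1 − 2 ΣLₑSₑ / (ΣLₑ + ΣSₑ + ε))` over background and plaque,
with C₀ = C₁ = 0.5 and ε = 1e-6 in the denominator so images lacking a
class entirely remain finite; per-image losses are averaged over the
batch. The optimizer is Adam with lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8,
batch size 4, 100 epochs — the fine-tuning regime, appropriate when the
encoder starts from pretrained weights. From-scratch smoke runs in the
test suite use lr 1e-3 and far fewer steps.

Cross-validation shuffles the sample list once (seeded) and deals folds
cyclically, so fold sizes differ by at most one; with 40 images and
k = 10, every fold holds exactly 4 test images. Per fold, the training
originals are expanded 8× (6 GIA + 2 CBVIA pairs); held-out images are
always evaluated un-augmented. Test-time ensembling averages the k fold
models' softmax maps pixelwise before the argmax — the mean of
normalized distributions is itself normalized, so the ensemble output
is still a probability map.

All training is bitwise reproducible on CPU for fixed seeds: phantom
content, fold assignment, weight init and epoch shuffling each derive
from an explicit seed.

## Augmentation conventions

The ±30° rotations are about the image center with the canvas kept at
the input size and out-of-canvas regions filled with 0; images use
bilinear interpolation, labels nearest-neighbor re-binarized at 0.5, so
labels stay strictly {0, 1}. CBVIA reuses the plaque label unchanged —
plaque lies inside the vessel by construction, so masking cannot orphan
label pixels; a label pixel outside the vessel mask raises an error
rather than being clipped silently. GIA is not composed on top of CBV
images beyond the single vertical flip.

## Evaluation conventions

Boundaries for the modified Hausdorff distance are 4-connectivity inner
boundaries with the image border counting as background. MHD is
reported in pixels unless a pixel spacing (mm/px) is supplied; areas
are pixel count × spacing². Degenerate cases: an empty-vs-empty mask
pair scores Dice = IoU = Acc = 1 and MHD is skipped (NaN, with a
warning); empty-vs-nonempty scores Dice = IoU = 0 with MHD likewise
skipped. Accuracy is computed over the full frame, which is why values
near 0.98 coexist with Dice near 0.7 — background dominates. The
paired t-test is two-sided with the p-value multiplied by the number of
comparisons and capped at 1; zero-variance zero-mean differences report
p = 1, zero-variance nonzero-mean differences p = 0 with a warning.

## Phantom generator

The generator emulates the gross structure the method relies on, at
128×128 by default (`scaled_to` rescales the recipe to other sizes,
e.g. 512×320):

- a horizontal vessel: dark lumen band (intensity 0.05) of half-height
  20 px around a gently undulating axis, flanked by bright wall bands
  (0.85) of half the lumen's thickness, inside echogenic tissue (~0.35);
- 2 elliptical plaques per image (semi-axes 6–16 px), anchored at the
  near or far lumen–wall interface and clipped to the lumen, at
  intermediate echogenicity — so plaque ⊆ vessel holds exactly;
- multiplicative unit-mean gamma speckle with shape 4 (SD = 1/√shape =
  0.5, a strong but realistic noise level for the classic fully
  developed-speckle surrogate; real noise statistics are not published
  for clinical scanners, so this is a free parameter chosen once);
- with probability 0.3 each, an acoustic-shadow column (Gaussian
  attenuation profile, 70 % intensity loss) and a bright horizontal
  reverberation-like streak.

What the phantom does **not** emulate: physically propagated wavefronts
and depth-dependent point-spread functions, heterogeneous plaque
composition (lipid/fiber/calcification textures), probe-dependent
geometry, and operator variability in the vessel masks. Passing the
learning tests therefore shows that the architecture, loss, protocol
and plumbing work end-to-end and that the network can exploit the
lumen-position prior; it does not certify clinical-grade accuracy on
real scans.

## Problem sizes in the test suite

The stochastic learning checks run at desk scale, chosen as the
package's own study conditions: an overfitting check (2 phantoms at
64×64, 200 Adam steps at lr 1e-3, training Dice > 0.95) and a
generalization check (20 phantoms at 128×128, 2-fold cross-validation,
3 epochs, pooled held-out Dice required to clear an all-background
predictor by a wide margin; observed ≈ 0.73 ± 0.20). Unit and property
tests use 32×32 models and masks up to 15×15 with brute-force oracles
(exhaustive tap summation for convolutions, all-pairs minima for MHD,
finite differences for every layer's gradients).

## Numerical choices and limitations

All tensors are float32; convolutions are computed as a sum over kernel
taps, each tap one BLAS matrix product on a strided view, which makes
dilation free and avoids im2col buffers. Batch-norm uses momentum 0.1
running statistics; evaluation always runs in inference mode. He
initialization for convolutions. The softmax subtracts the per-pixel
max before exponentiation.

Known limitations: no pretrained ImageNet weights ship with the package
(the loader accepts any correctly shaped `.npz`, and seeded random
initialization is the documented fallback), training at clinical sizes
(512×320, 100 epochs, 10 folds) is possible but slow on one CPU, and
the phantom's simplicity means reported phantom metrics should not be
compared directly against clinical-dataset figures.
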