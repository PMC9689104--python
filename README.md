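# hrunet

Automated segmentation of atherosclerotic plaque in B-mode carotid
ultrasound. Plaque in the carotid artery narrows the lumen and, when it
ruptures, causes stroke; outlining it in longitudinal ultrasound scans is
how clinicians quantify stenosis and plaque burden, but manual contouring
is slow and rater-dependent. This package implements **HRU-Net**, an
encoder–decoder convolutional network built for exactly this setting —
small, noisy datasets — together with the data augmentation, training
protocol and evaluation suite around it, and a synthetic phantom generator
that stands in for clinical images (which are typically private).

The pieces, in the field's standard notation:

- **Encoder transfer learning.** A ResNet-50 trunk (residual mapping
  `y = F(x, W) + x`) serves as encoder; its block outputs
  (64/256/512/1024/2048 channels at H/2 … H/32) are compressed by 1×1
  convolutions to 32/64/96/128/128 channels before the skip connections.
  Pretrained weights can be loaded from an `.npz` file and fine-tuned;
  without a weight file the encoder starts from seeded random init.
- **Hybrid atrous convolutions (HAC).** Dilated 3×3 convolutions sample
  taps `r` pixels apart, so a stride-1 stack sees
  `RF = 1 + Σ rᵢ(Kᵢ−1)` input pixels. A HAC block runs parallel
  branches at rates 1, 2, 3, 5 plus a cascaded rate-1→2→3 chain (RF
  13×13), fuses them with a 1×1 convolution, and is applied to the three
  deepest encoder levels by default (placement is configurable for
  ablations).
- **Mask-consistent augmentation.** GIA: identity, horizontal/vertical
  flips, 180° and ±30° rotations of image and label alike (6 variants).
  CBVIA: the image multiplied by its vessel mask — the cropped blood
  vessel, encoding the prior that plaque only occurs inside the artery —
  plus its vertical flip (2 variants). 8 training pairs per original;
  evaluation always sees un-augmented images.
- **Training and ensembling.** Weighted Dice loss
  `L = Σₑ Cₑ(1 − 2ΣLₑSₑ/(ΣLₑ+ΣSₑ))` with C₀ = C₁ = 0.5, Adam
  (lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8), batch 4, 100 epochs, 10-fold
  cross-validation; test-time prediction averages the k fold models'
  softmax maps pixelwise.
- **Evaluation.** Dice, IoU, pixel accuracy, modified Hausdorff distance
  `MHD = max(d(Lb,Sb), d(Sb,Lb))` with `d` the mean-of-minima boundary
  distance, plaque-area error ΔTPA, Bland–Altman agreement, and paired
  t-tests with Bonferroni correction.

Everything — including all convolution forward/backward passes, batch
normalization, pooling, bilinear upsampling and Adam — is implemented in
NumPy, so the package runs on any CPU with no deep-learning framework.

## Worked example

`examples/05_train_and_evaluate.py` runs the full pipeline at desk
scale — 10 phantoms at 64×64, 2 folds, 6 epochs:

```
metric         mean       SD
dice          0.717    0.064
iou           0.563    0.078
acc           0.981    0.007
mhd           2.114    1.029
delta_tpa    14.800   55.620
```

Each image is scored by the fold model that never saw it: `dice`/`iou`
measure overlap with the ground-truth plaque mask (1 is perfect), `acc`
is full-frame pixel agreement, `mhd` the mean boundary disagreement in
pixels (lower is better), and `delta_tpa` the signed plaque-area error
in px². A scaled-up run (20 phantoms, 128×128, 3 epochs, the
acceptance-test conditions) reaches held-out Dice ≈ 0.73 ± 0.20. The
other examples (`examples/01…06`) each demonstrate one capability:
phantom generation, augmentation bookkeeping (40 originals → 320
pairs), receptive-field arithmetic, model anatomy, and
ensembling/agreement statistics.

The same pipeline is scriptable from the shell:

```sh
hrunet phantom --n 40 --height 128 --width 128 --seed 7 --out data/
hrunet crossval --config cfg.yaml --out runs/
hrunet predict --models runs/fold0.npz --models runs/fold1.npz \
    --image data/img_000.png --out pred.png
hrunet evaluate --pred preds/ --gt labels/ --out metrics.csv
hrunet ablate --config cfg.yaml --counts 0,1,2,3 --out runs/ablation/
```

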