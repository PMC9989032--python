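# pestaug

Manipulation-based data augmentation for insect-pest image classification.

Field datasets of crop pests — here, the six common insect pests of castor
(*Ricinus communis* L.): castor semilooper, Bihar hairy caterpillar,
leafhopper, thrips, whitefly and leaf miner — are small (tens of images per
class) and imbalanced, which starves convolutional classifiers of training
signal. `pestaug` expands such a dataset with *label-preserving* pixel
manipulations: for every transform *f* applied to a labeled image,

```
y_aug = y_src,    x_aug = f(x_src)
```

so the class label never changes while the raster does. The package is
aimed at practitioners building small-data image classifiers (precision
agriculture and beyond) who need reproducible, auditable augmentation
rather than ad-hoc in-loop randomness.

## What it implements

- **Atomic operators** (`pestaug.transforms`): center rotation
  (R(θ) = [[cos θ, −sin θ], [sin θ, cos θ]] about the raster center),
  horizontal/vertical flips, additive Gaussian noise, per-channel histogram
  equalization, central-crop zoom (scale-in) and reflect-pad shrink
  (scale-out), same-class mixup (X′ = λ·Xᵢ + (1−λ)·Xⱼ, λ = 0.2), and
  fancy-PCA channel-intensity perturbation with components retained to 95 %
  cumulative variance. Every operator preserves label, dimensions and the
  8-bit intensity range, and appends itself to the record's provenance
  chain.
- **The cascade pipeline** (`pestaug.cascade`): per pass, three random
  rotations; one stored, one histogram-equalized, one noised, and both
  transformed branches additionally zoomed — five outputs per pass. Three
  passes plus the retained original expand every source image exactly
  16-fold (54 → 864, 44 → 704).
- **Eleven benchmark strategies** (`pestaug.strategies`): baseline (0),
  rotation, flips, contrast enhancement, noise, PCA, mixup, scale in/out,
  rotation+scaling, rotation+flip+scaling, and the cascade (10), each as a
  seeded, reproducible preset, plus a comparison harness that trains one
  classifier per strategy and scores all of them on the same held-out
  unmodified originals.
- **Dataset I/O** (`pestaug.dataset_io`): class-per-subdirectory image
  folders, lossless PNG output with a provenance manifest, bilinear
  resizing, and a stratified, seeded 7:3 train/validation split with no
  sample overlap.
- **Synthetic fixtures** (`pestaug.synthetic`): a seeded generator of
  pest-like labeled images reproducing the field dataset's structure
  (6 classes, counts 54/84/49/69/72/44, total 372) so the whole pipeline is
  testable without the original photographs.
- **Evaluation harness** (`pestaug.evaluation`): a frozen backbone feeding
  the modified fully connected head (dense-512-ReLU, dropout 0.5, softmax),
  trained with Adam (lr 0.001, batch 32) on categorical cross-entropy, with
  per-epoch accuracy curves. The bundled `tiny` backbone is a seeded
  random-filter convolutional stack that needs no deep-learning framework;
  `vgg16`/`vgg19`/`resnet50` presets (inputs 224/224/124 px) attach when the
  optional tensorflow dependency is installed. Accuracy is
  correct predictions / total predictions; a strategy's **contribution** is
  100·(acc_aug − acc_base)/acc_base, truncated to two decimals.

## Worked example

```python
from pestaug import (CascadeConfig, TrainConfig, augment_class,
                     contribution_percent, generate_castipest_like,
                     run_comparison)

# one 54-image class expands 16-fold
ds = generate_castipest_like({"AJ": 54}, size=64, seed=1)
print(len(augment_class(ds.records, CascadeConfig(master_seed=1))))
# 864

# baseline vs cascade on the full 372-image synthetic fixture set
fixture = generate_castipest_like(size=128, seed=0)
table = run_comparison(fixture, [0, 10], TrainConfig(epochs=20, seed=0))
print(table.to_string(index=False))
#  id              name  n_train  val_accuracy
#   0   No augmentation      260      0.973214
#  10 Proposed approach     4160      1.000000

# contribution of augmentation, in percent of the baseline
print(contribution_percent(100 * 1.0, 100 * 0.973214))
# 2.75
```

The first number is the cascade count law in action: 54 sources × (5
outputs per pass × 3 passes + the original) = 864 augmented images. The
table shows the desk-scale comparison: the cascade-augmented training set
(4 160 images from the 260 training originals) generalizes at least as well
to the 112 held-out originals as training on the originals alone, and the
final line converts that gap into a baseline-relative contribution percent.

Equivalent shell commands: `pestaug synth`, `pestaug augment --strategy 10`,
`pestaug split`, `pestaug benchmark --ids 0,10`, `pestaug eval` (see
`pestaug --help`).

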