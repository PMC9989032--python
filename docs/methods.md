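# Methods

## The augmentation model

`pestaug` treats augmentation as a family of label-preserving operators on
8-bit RGB rasters: a transform maps `(pixels, label)` to
`(f(pixels), label)`. The package enforces this contract structurally —
every operator returns a new `ImageRecord` carrying the input's label and
`source_id`, with the operation appended to an append-only provenance
chain. The chain is what makes the downstream leakage guard possible: an
augmented image always knows which raw image it derives from, so a
comparison harness can prove that no derivative of a held-out image reached
training.

All operators compute in floating point and quantize once on output:
round half away from zero, clip to [0, 255], cast to uint8. A single
quantization rule keeps every pipeline bit-reproducible across runs and
platforms.

### Seeding

A master seed spawns one independent substream per
(source image, operation index) via `numpy` `SeedSequence` spawn keys (the
source id enters through a CRC-32 hash). Results are therefore independent
of the order in which images are processed and safe to parallelize, and the
same master seed reproduces a byte-identical augmented dataset.

## Atomic operators

| operator | parameters (default) | notes |
| --- | --- | --- |
| `rotate` | θ degrees; bilinear; reflect fill | about the raster center, canvas unchanged; θ reduced mod 360; multiples of 90° on square rasters are exact `rot90` permutations, so rotate-then-unrotate at right angles is lossless |
| `flip` | axis ∈ {horizontal, vertical} | involution |
| `gaussian_noise` | σ = 10, mean = 0 (0–255 scale) | i.i.d. per pixel and channel; σ = 10 is visually perceptible without destroying class structure and is a config knob |
| `hist_equalize` | — | per channel: `out(v) = round((cdf(v) − cdf_min)/(N − cdf_min) · 255)`; monotone; a constant channel is returned unchanged (the formula's denominator is 0 there, and identity is the only label-safe convention); idempotent up to 1 level |
| `scale_in` | zoom = 1.25 | central crop of side ⌊side/zoom⌋, bilinear resize back; zoom 1 is the identity |
| `scale_out` | zoom = 1.25 | reflect-pad to side·zoom, resize back (object appears smaller) |
| `mixup` | λ = 0.2, same-class partner | per-pixel convex combination; cross-class pairs and self-pairing are rejected, which is what makes mixup label-preserving here; a partner of different size is resized to the first image |
| `pca_augment` | 95 % variance, α_σ = 0.1, working side 64 | see below |

### Fancy-PCA details

The 3×3 covariance of RGB triples is estimated over the whole dataset with
pixels scaled to [0, 1], at a fixed 64×64 working resolution (covariance of
a color distribution is insensitive to resolution; the fixed size bounds
cost on arbitrarily large inputs). Components are retained up to the
smallest k whose cumulative explained variance reaches the threshold
(rank-deficient covariances reach 1.0 before k = 3; a grayscale dataset
replicated across channels selects k = 1 at the 0.95 default). Each image
receives a single color shift `255 · P_k α` with `α_j ~ N(0, sd = α_σ·λ_j)`
constant over pixels — the classic eigenvalue-scaled intensity
perturbation. On the [0, 1] scale typical eigenvalues are ~10⁻²,
so the default perturbation is a subtle global color cast; α_σ is exposed
for stronger effects. A zero-variance dataset (single constant image) is
rejected with a validation error naming the degenerate covariance.

## The cascade pipeline

Per pass over one source image: draw three independent rotation angles
uniformly from [0°, 360°); store the first rotated copy; histogram-equalize
the second and store it; add Gaussian noise to the third and store it; then
scale-in both transformed copies and store those too. Five outputs per
pass, each reachable by exactly one of the provenance paths

```
rotate
rotate → hist_equalize
rotate → hist_equalize → scale_in
rotate → gaussian_noise
rotate → gaussian_noise → scale_in
```

With the default `rounds = 3` and `include_original = True` the expansion
factor is 5·3 + 1 = 16, which reproduces the 54 → 864 and 44 → 704
class expansions exactly; the count law `n · (5·rounds + include_original)`
holds for every configuration. The assignment of the three rotated copies
to {store, enhance, noise} is positional (first/second/third draw): any
deterministic rule suffices and the positional one is seed-reproducible.

Note the two rotation ranges are deliberate: the cascade draws from the
full circle, while the *benchmark* rotation presets draw from [0°, 150°],
honoring both conventions in their respective contexts.

## Benchmark strategies

Strategies 1–9 emit a fixed fan-out of two new images per source (composed
strategies chain their operators within each draw), with the originals
retained by default, so the benchmark training sets are mutually comparable
in size; strategy 10 is the cascade. Two consequences worth knowing:
contrast enhancement (strategy 3) is deterministic, so its two draws are
identical copies — kept for size comparability; and "scale in/out"
(strategy 7) alternates one zoom-in crop and one reflect-pad zoom-out per
source.

`run_comparison` evaluates strategies the way such comparisons must be run
to mean anything: the originals are split 7:3 once, every strategy augments
*only* the training portion, and all strategies are scored on the same
unmodified held-out originals. The harness audits provenance (`source_id`
of every training record must belong to the train split) and raises a
leakage error otherwise.

## Dataset I/O

Splits are stratified by class by default: per-class counts here are small
(44–84) and imbalanced, and an unstratified split could starve a class's
validation set. The per-class train count is round-half-up of 0.7·n,
clamped so both sides stay non-empty. Written datasets are always PNG so
augmented pixels survive the round trip bit-exactly; JPEG/BMP are accepted
on input only. The manifest CSV records file, class, source id, the
serialized transform chain and seeds, and `load_image_folder` restores full
provenance from it when present.

## Synthetic fixtures

The generator emulates the *structure* of the field dataset — six classes,
counts 54/84/49/69/72/44 (total 372), class-distinguishable appearance —
not pest morphology. Each image is a smooth two-color foliage background
plus one elliptical body whose hue, elongation and spot density come from
the class archetype, with per-seed jitter in position, orientation, scale
and hue. The archetypes are separable by color by construction (a mean-color
nearest-centroid classifier clearly beats the 1/6 chance level on a 7:3
split), so augmentation-versus-baseline comparisons on fixtures are
meaningful. What passing fixtures does **not** show: robustness to real
photographic nuisances (occlusion, specular highlights, background clutter,
camera noise statistics) or to fine-grained inter-species similarity; the
default fixture resolution is 128×128, far below field photographs.

## Evaluation harness

The classifier is a frozen feature extractor plus the trainable two-layer
head: dense 512 with ReLU and dropout 0.5, then a softmax output layer —
with dropout 0.3 at the backbone–head junction (the protocol's stated
dropout range 0.3–0.5 is realized as 0.3 at the junction and 0.5 on the
512-unit layer). Training uses Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch
size 32, categorical cross-entropy, accuracy recorded every epoch.

The bundled `tiny` backbone is two 3×3 convolution + ReLU + 2×2 max-pool
blocks (8 then 16 filters) with fixed He-initialized seeded random weights,
on 32×32 inputs (576 features). Random convolutional features are a
standard cheap stand-in for a pretrained extractor at desk scale; only the
head trains, exactly as with the frozen named backbones. Two numerical
choices matter for generalization with few samples:

- features are centered per dimension but scaled by a single global
  standard deviation — per-feature unit-variance scaling would amplify
  near-dead ReLU dimensions into pure noise axes and wreck validation
  accuracy;
- a small decoupled weight decay (1e-3) is applied to the dense matrices.

Named backbones (`vgg16`, `vgg19` at 224 px; `resnet50` at 124 px, as the
protocol specifies even though 224 is canonical for ResNet) are built with
frozen convolutional weights and the same head when tensorflow is
installed, and raise an explicit capability error otherwise; every other
module is independent of any deep-learning framework. The exact
freeze boundary that would reproduce the published trainable-parameter
counts is not derivable from the protocol description, so freezing is
all-convolutional by default with `unfreeze_last_n_blocks` exposed.

Contribution percentages are **truncated** (toward zero), not rounded, to
two decimals: truncation is the rule that reproduces both published values
(15.54 from 15.5498…, 5.73 from 5.7352…) from the published accuracies.

## Problem sizes used in the test suite

The directional comparison (cascade vs. no augmentation) runs on the full
372-image fixture set at 128×128 with the tiny backbone, 20 epochs, batch
32, over 5 seeds — about two minutes on one CPU; the augmented training set
is 4 160 images. These sizes are the package's scaled-down analog of the
full protocol (100 epochs, GPU-scale backbones) and are the documented
conditions under which the directional claim — mean augmented validation
accuracy ≥ mean baseline — is tested.

## Known limitations

- Four of the six published per-class augmented counts (84 → 1,332,
  49 → 780, 69 → 1,100, 72 → 1,136) are not integer multiples of the ×16
  factor implied by the other two (54 → 864, 44 → 704); the discrepancy is
  unexplained at the source (plausibly post-hoc near-duplicate removal).
  The pipeline implements the exact count law; a duplicate-filter hook is
  not enabled by default.
- Absolute published accuracies are not reproducible without the original
  photographs and GPU-scale training; the harness supports the protocol but
  the bundled tests make directional claims only.
- Endpoint inclusion and angular granularity of the benchmark rotation
  range [0°, 150°] are unspecified at the source; the preset samples the
  closed interval uniformly and continuously.
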