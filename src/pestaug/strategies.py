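"""The eleven benchmark augmentation strategies as named, reproducible presets.

Strategy 0 is the no-augmentation baseline; 1–9 are single or composed
classic operators (rotation, flips, contrast enhancement, noise, fancy-PCA,
same-class mixup, scale in/out, and rotation/flip/scale compositions); 10 is
the proposed cascade pipeline.  Strategies 1–9 emit a fixed fan-out of two
new images per source (composed strategies chain their operators within each
draw) so that all benchmark training sets are comparable in size; the
original images are retained by default.

``run_comparison`` evaluates each strategy the way the comparison was
designed: the original images are split 7:3, each strategy augments ONLY the
training portion, and every strategy is scored on the same unmodified
held-out originals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .cascade import CascadeConfig, augment_dataset
from .core import ImageRecord, LabeledDataset, ValidationError, substream
from .dataset_io import SplitSpec, split_train_val
from .evaluation import HeadSpec, TrainConfig, build_classifier, train_and_evaluate
from .transforms import (
    MixupSpec,
    NoiseSpec,
    PCASpec,
    RotationSpec,
    ScaleSpec,
    flip,
    gaussian_noise,
    hist_equalize,
    mixup,
    pca_augment,
    rotate,
    scale_in,
    scale_out,
)

__all__ = ["StrategyPreset", "STRATEGIES", "build_strategy", "run_comparison"]

#: Rotation range of the BENCHMARK rotation presets (degrees); the proposed
#: cascade instead draws from the full [0, 360) circle.
BENCHMARK_ROTATION_RANGE = (0.0, 150.0)
FAN_OUT = 2


@dataclass(frozen=True)
class StrategyPreset:
    """One benchmark augmentation configuration."""

    id: int
    name: str
    builder: Callable[[LabeledDataset, int, bool], LabeledDataset]


def _with_originals(new: list[ImageRecord], dataset: LabeledDataset,
                    include_original: bool) -> LabeledDataset:
    records = ([rec.copy() for rec in dataset] if include_original else []) + new
    return LabeledDataset(records, list(dataset.classes))


def _per_image(dataset, seed, include_original, draw):
    """Apply ``draw(record, rng, draw_index)`` FAN_OUT times per source image."""
    new: list[ImageRecord] = []
    for rec in dataset:
        for j in range(FAN_OUT):
            rng = substream(seed, rec.source_id, j)
            new.append(draw(rec, rng, j))
    return _with_originals(new, dataset, include_original)


def _s0_baseline(dataset, seed, include_original):
    return LabeledDataset([r.copy() for r in dataset], list(dataset.classes))


def _s1_rotation(dataset, seed, include_original):
    lo, hi = BENCHMARK_ROTATION_RANGE

    def draw(rec, rng, j):
        return rotate(rec, RotationSpec(theta=float(rng.uniform(lo, hi))))
    return _per_image(dataset, seed, include_original, draw)


def _s2_flips(dataset, seed, include_original):
    def draw(rec, rng, j):
        return flip(rec, "vertical" if j == 0 else "horizontal")
    return _per_image(dataset, seed, include_original, draw)


def _s3_enhancement(dataset, seed, include_original):
    def draw(rec, rng, j):
        return hist_equalize(rec)
    return _per_image(dataset, seed, include_original, draw)


def _s4_noise(dataset, seed, include_original):
    def draw(rec, rng, j):
        return gaussian_noise(rec, NoiseSpec(), rng)
    return _per_image(dataset, seed, include_original, draw)


def _s5_pca(dataset, seed, include_original):
    spec = PCASpec(variance_threshold=0.95)
    new: list[ImageRecord] = []
    for j in range(FAN_OUT):
        new.extend(pca_augment(dataset, spec, master_seed=seed * FAN_OUT + j).records)
    return _with_originals(new, dataset, include_original)


def _s6_mixup(dataset, seed, include_original):
    spec = MixupSpec(lambda_weight=0.2)

    def draw(rec, rng, j):
        peers = [r for r in dataset.by_class(rec.label) if r.source_id != rec.source_id]
        if not peers:
            raise ValidationError(
                f"mixup needs >= 2 images in class {rec.label!r}")
        partner = peers[int(rng.integers(0, len(peers)))]
        return mixup(rec, partner, spec)
    return _per_image(dataset, seed, include_original, draw)


def _s7_scale(dataset, seed, include_original):
    def draw(rec, rng, j):
        op = scale_in if j == 0 else scale_out
        return op(rec, ScaleSpec(zoom=1.25))
    return _per_image(dataset, seed, include_original, draw)


def _s8_rotation_scaling(dataset, seed, include_original):
    lo, hi = BENCHMARK_ROTATION_RANGE

    def draw(rec, rng, j):
        r = rotate(rec, RotationSpec(theta=float(rng.uniform(lo, hi))))
        return scale_in(r, ScaleSpec(zoom=1.25))
    return _per_image(dataset, seed, include_original, draw)


def _s9_rotation_flip_scaling(dataset, seed, include_original):
    lo, hi = BENCHMARK_ROTATION_RANGE

    def draw(rec, rng, j):
        r = rotate(rec, RotationSpec(theta=float(rng.uniform(lo, hi))))
        r = flip(r, "horizontal" if j == 0 else "vertical")
        return scale_in(r, ScaleSpec(zoom=1.25))
    return _per_image(dataset, seed, include_original, draw)


def _s10_proposed(dataset, seed, include_original):
    config = CascadeConfig(master_seed=seed, include_original=include_original)
    return augment_dataset(dataset, config)


STRATEGIES: dict[int, StrategyPreset] = {
    0: StrategyPreset(0, "No augmentation", _s0_baseline),
    1: StrategyPreset(1, "Rotation", _s1_rotation),
    2: StrategyPreset(2, "Vertical + horizontal flips", _s2_flips),
    3: StrategyPreset(3, "Contrast enhancement", _s3_enhancement),
    4: StrategyPreset(4, "Noise", _s4_noise),
    5: StrategyPreset(5, "PCA", _s5_pca),
    6: StrategyPreset(6, "Mixup", _s6_mixup),
    7: StrategyPreset(7, "Scale in/out", _s7_scale),
    8: StrategyPreset(8, "Rotation + scaling", _s8_rotation_scaling),
    9: StrategyPreset(9, "Rotation + flip + scaling", _s9_rotation_flip_scaling),
    10: StrategyPreset(10, "Proposed approach", _s10_proposed),
}


def build_strategy(dataset: LabeledDataset, id: int, seed: int,
                   include_original: bool = True) -> LabeledDataset:
    """Materialize the augmented dataset for one benchmark strategy id (0-10)."""
    if id not in STRATEGIES:
        raise ValidationError(f"strategy id must be in 0..10; got {id}")
    return STRATEGIES[id].builder(dataset, seed, include_original)


def run_comparison(dataset: LabeledDataset, ids: list[int],
                   eval_config: TrainConfig) -> pd.DataFrame:
    """Train one classifier per strategy and score all on the same held-out originals.

    The original dataset is split 7:3 (stratified, seeded from the eval
    config); each strategy augments only the training portion, so no
    derivative of a validation image can reach training (audited).  Returns
    one row per id: (id, name, n_train, val_accuracy).
    """
    if not ids:
        raise ValidationError("ids must be non-empty")
    if len(dataset) == 0:
        raise ValidationError("dataset must be non-empty")
    train, val = split_train_val(dataset, SplitSpec(seed=eval_config.seed))
    val_sources = val.source_ids()

    rows = []
    for sid in ids:
        augmented = build_strategy(train, sid, seed=eval_config.seed)
        leaked = augmented.source_ids() & val_sources
        if leaked:
            raise ValidationError(
                f"strategy {sid} produced derivatives of validation images: "
                f"{sorted(leaked)[:3]}")
        head = HeadSpec(output_units=len(dataset.classes))
        clf = build_classifier(head, eval_config)
        result = train_and_evaluate(clf, augmented, val, eval_config)
        rows.append({"id": sid, "name": STRATEGIES[sid].name,
                     "n_train": len(augmented),
                     "val_accuracy": result.final_val_accuracy})
    return pd.DataFrame(rows)
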