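"""The cascaded manipulation pipeline that expands a pest-image class.

One cascade pass over a source image draws three independent random
rotations.  The first rotated copy is stored as-is; the second is contrast-
enhanced (per-channel histogram equalization) and stored; the third receives
additive Gaussian noise and is stored; then both transformed branches are
centrally zoomed (scale-in) and stored again.  That is five stored outputs
per pass:

    rotation
    rotation -> enhance
    rotation -> enhance -> scale
    rotation -> noise
    rotation -> noise -> scale

With the default three passes per source image plus the retained original,
every source image expands into exactly 16 augmented records, so a class of
54 images becomes 864 and a class of 44 becomes 704.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageRecord, LabeledDataset, ValidationError, substream
from .transforms import (
    NoiseSpec,
    RotationSpec,
    ScaleSpec,
    gaussian_noise,
    hist_equalize,
    rotate,
    scale_in,
)

__all__ = ["CascadeConfig", "cascade_one", "augment_class", "augment_dataset"]

OUTPUTS_PER_ROUND = 5


@dataclass(frozen=True)
class CascadeConfig:
    """All parameters of the cascade pipeline."""

    rounds: int = 3
    rotation_range: tuple[float, float] = (0.0, 360.0)  # degrees, half-open
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    scale: ScaleSpec = field(default_factory=ScaleSpec)
    include_original: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValidationError("cascade rounds must be >= 1")
        lo, hi = self.rotation_range
        if not lo < hi:
            raise ValidationError("rotation range must be a nonempty interval")

    def expansion_factor(self) -> int:
        """Outputs per source image: 5 per round, plus the retained original."""
        return OUTPUTS_PER_ROUND * self.rounds + (1 if self.include_original else 0)


def cascade_one(image: ImageRecord, config: CascadeConfig) -> list[ImageRecord]:
    """Run the full cascade on one source image.

    Per round: three random rotation angles are drawn from
    ``config.rotation_range``; copy 1 is stored, copy 2 is enhanced and
    stored, copy 3 is noised and stored, and the enhanced and noisy copies
    are each scale-in zoomed and stored.  The untouched original is appended
    last when ``include_original`` is set.  Randomness comes from substreams
    of ``config.master_seed`` keyed by (source_id, operation index), so the
    output is independent of processing order.
    """
    lo, hi = config.rotation_range
    out: list[ImageRecord] = []
    op_index = 0
    for _ in range(config.rounds):
        angle_rng = substream(config.master_seed, image.source_id, op_index)
        thetas = angle_rng.uniform(lo, hi, size=3)
        op_index += 1

        r1 = rotate(image, RotationSpec(theta=float(thetas[0])))
        r2 = rotate(image, RotationSpec(theta=float(thetas[1])))
        r3 = rotate(image, RotationSpec(theta=float(thetas[2])))

        enhanced = hist_equalize(r2)
        noise_seed = substream(config.master_seed, image.source_id, op_index)
        op_index += 1
        noisy = gaussian_noise(r3, config.noise, noise_seed)

        out.append(r1)
        out.append(enhanced)
        out.append(noisy)
        out.append(scale_in(enhanced, config.scale))
        out.append(scale_in(noisy, config.scale))
    if config.include_original:
        out.append(image.copy())
    return out


def augment_class(images: list[ImageRecord], config: CascadeConfig) -> list[ImageRecord]:
    """Cascade every image of one class; output count is ``n * expansion_factor()``."""
    labels = {img.label for img in images}
    if len(labels) > 1:
        raise ValidationError(f"augment_class requires a single class; got {sorted(labels)}")
    out: list[ImageRecord] = []
    for img in images:
        out.extend(cascade_one(img, config))
    return out


def augment_dataset(dataset: LabeledDataset, config: CascadeConfig) -> LabeledDataset:
    """Per-class cascade expansion; the class set is unchanged."""
    records: list[ImageRecord] = []
    for cls in dataset.classes:
        records.extend(augment_class(dataset.by_class(cls), config))
    return LabeledDataset(records, list(dataset.classes))
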