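"""Seeded procedural generator of labeled pest-like image fixtures.

The real castor insect-pest dataset (372 curated photographs in six
imbalanced classes) is not publicly deposited, so this module generates a
structurally equivalent stand-in: six classes with the same per-class counts
(54, 84, 49, 69, 72, 44), variable appearance, and class-distinguishable
color/shape/texture.  Each image is a textured foliage background plus one
elliptical "pest" body whose hue, elongation and spot texture are drawn from
the class archetype, with per-seed jitter in position, orientation, scale
and hue.  Fixtures emulate dataset STRUCTURE (classes, counts, imbalance,
learnable class signal), not real pest morphology.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .core import ImageRecord, LabeledDataset, ValidationError

__all__ = ["ClassArchetype", "ARCHETYPES", "DEFAULT_COUNTS",
           "generate_image", "generate_castipest_like"]


@dataclass(frozen=True)
class ClassArchetype:
    """Appearance parameters of one synthetic pest class."""

    name: str
    body_hue: tuple[int, int, int]          # base RGB of the body
    body_aspect: float                      # ellipse elongation (major/minor)
    spot_density: float                     # spots per 1000 body pixels
    background_palette: tuple[tuple[int, int, int], tuple[int, int, int]]


# Six archetypes named after the field dataset's class abbreviations
# (castor semilooper, Bihar hairy caterpillar, leafhopper, thrips, whitefly,
# leaf miner).  Appearance parameters are invented but pairwise distinct.
ARCHETYPES: dict[str, ClassArchetype] = {
    "AJ": ClassArchetype("AJ", (140, 60, 40), 3.2, 2.0, ((40, 90, 35), (70, 130, 50))),
    "SO": ClassArchetype("SO", (90, 60, 20), 2.6, 8.0, ((50, 100, 40), (90, 140, 60))),
    "EF": ClassArchetype("EF", (150, 200, 90), 1.8, 0.5, ((30, 80, 30), (60, 120, 45))),
    "RS": ClassArchetype("RS", (40, 30, 50), 2.2, 4.0, ((60, 110, 45), (100, 150, 70))),
    "TR": ClassArchetype("TR", (235, 235, 225), 1.4, 0.2, ((45, 95, 40), (80, 135, 55))),
    "LR": ClassArchetype("LR", (200, 170, 60), 2.9, 1.0, ((35, 85, 35), (65, 125, 50))),
}

#: Per-class image counts of the emulated field dataset (total 372).
DEFAULT_COUNTS: dict[str, int] = {
    "AJ": 54, "SO": 84, "EF": 49, "RS": 69, "TR": 72, "LR": 44,
}


def _background(rng: np.random.Generator, size: int,
                palette: tuple[tuple[int, int, int], tuple[int, int, int]]) -> np.ndarray:
    """Smooth random blend between the two palette colors plus fine grain."""
    coarse = rng.random((8, 8))
    field = np.asarray(
        Image.fromarray((coarse * 255).astype(np.uint8), mode="L")
        .resize((size, size), Image.BILINEAR), dtype=np.float64) / 255.0
    c0 = np.asarray(palette[0], dtype=np.float64)
    c1 = np.asarray(palette[1], dtype=np.float64)
    bg = field[..., None] * c1 + (1.0 - field[..., None]) * c0
    bg += rng.normal(0.0, 6.0, size=bg.shape)
    return bg


def generate_image(archetype: ClassArchetype, size: int, seed: int) -> ImageRecord:
    """One synthetic pest image; deterministic per (archetype, size, seed)."""
    if size < 32:
        raise ValidationError("fixture size must be >= 32 pixels")
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(zlib.crc32(archetype.name.encode()), size))
    rng = np.random.default_rng(ss)

    canvas = _background(rng, size, archetype.background_palette)

    # body geometry with per-seed jitter
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
    major = rng.uniform(0.18, 0.28) * size
    minor = major / (archetype.body_aspect * rng.uniform(0.85, 1.15))
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    mask = (u / major) ** 2 + (v / minor) ** 2 <= 1.0

    hue = np.asarray(archetype.body_hue, dtype=np.float64)
    hue = hue + rng.normal(0.0, 8.0, size=3)
    body = hue[None, None, :] + rng.normal(0.0, 5.0, size=(size, size, 3))
    canvas[mask] = body[mask]

    # darker spots scattered on the body
    n_spots = rng.poisson(archetype.spot_density * mask.sum() / 1000.0)
    ys, xs = np.nonzero(mask)
    if len(ys) and n_spots:
        pick = rng.integers(0, len(ys), size=n_spots)
        radius = max(1, size // 48)
        for sy, sx in zip(ys[pick], xs[pick]):
            spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= radius ** 2
            canvas[spot & mask] *= 0.55

    pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return ImageRecord(pixels=pixels, label=archetype.name,
                       source_id=f"{archetype.name}/synthetic_{seed}")


def generate_castipest_like(counts: dict[str, int] | None = None,
                            size: int = 128, seed: int = 0) -> LabeledDataset:
    """Dataset with the requested (default: field-dataset) per-class counts."""
    counts = dict(DEFAULT_COUNTS) if counts is None else dict(counts)
    for cls, n in counts.items():
        if cls not in ARCHETYPES:
            raise ValidationError(f"unknown class name {cls!r}")
        if n < 0:
            raise ValidationError("class counts must be non-negative")
    classes = [c for c in ARCHETYPES if c in counts]
    records: list[ImageRecord] = []
    for cls in classes:
        arch = ARCHETYPES[cls]
        for i in range(counts[cls]):
            child = np.random.SeedSequence(
                entropy=int(seed), spawn_key=(zlib.crc32(cls.encode()), i))
            img_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)
            rec = generate_image(arch, size, img_seed)
            records.append(ImageRecord(rec.pixels, cls, f"{cls}/synthetic_{i:04d}"))
    return LabeledDataset(records, classes)
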