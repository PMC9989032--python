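"""Image-folder datasets: loading, writing with a manifest, resizing, splitting.

Datasets live on disk as one subdirectory per class containing 8-bit RGB
raster images.  Written datasets are always PNG (lossless, so augmented
pixels round-trip bit-exactly) plus a manifest CSV recording file, class,
source image, provenance chain and seed.  The train/validation split is a
stratified, seeded 7:3 partition with no sample overlap.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .core import ImageRecord, LabeledDataset, TransformSpec, ValidationError

__all__ = [
    "SplitSpec", "load_image_folder", "split_train_val", "resize", "write_dataset",
    "parse_chain",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation split parameters (default 7:3)."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train fraction must lie in (0, 1)")


def load_image_folder(path: str | Path) -> LabeledDataset:
    """Load a class-per-subdirectory folder of images.

    The subdirectory name is the class label and the file's path relative to
    ``path`` is its source_id.  Classes and files are ordered
    lexicographically, so repeated loads produce identical record order.
    """
    root = Path(path)
    if not root.is_dir():
        raise ValidationError(f"dataset folder {root} does not exist")
    classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise ValidationError(f"{root} contains no class subdirectories")

    # a manifest written by write_dataset restores full provenance
    provenance: dict[str, tuple[str, tuple[TransformSpec, ...]]] = {}
    manifest = root / "manifest.csv"
    if manifest.is_file():
        with manifest.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                provenance[row["file"]] = (row["source_id"],
                                           parse_chain(row["transform_chain"]))

    records: list[ImageRecord] = []
    for cls in classes:
        files = sorted(p for p in (root / cls).iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            import warnings
            warnings.warn(f"class directory {cls!r} contains no images", stacklevel=2)
        for f in files:
            try:
                img = Image.open(f).convert("RGB")
            except Exception as exc:  # undecodable file: name it
                raise ValidationError(f"cannot decode image file {f}: {exc}") from exc
            rel = str(f.relative_to(root))
            source_id, chain = provenance.get(rel, (rel, ()))
            records.append(ImageRecord(
                pixels=np.asarray(img, dtype=np.uint8),
                label=cls,
                source_id=source_id,
                transform_chain=chain,
            ))
    return LabeledDataset(records, classes)


def split_train_val(dataset: LabeledDataset,
                    spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint stratified partition; per-class train count = round-half-up(f*n)."""
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    if spec.stratified:
        for cls in dataset.classes:
            idx = [i for i, r in enumerate(dataset.records) if r.label == cls]
            if len(idx) < 2:
                raise ValidationError(
                    f"class {cls!r} has {len(idx)} record(s); stratified split needs >= 2")
            perm = rng.permutation(len(idx))
            n_train = int(math.floor(spec.train_fraction * len(idx) + 0.5))
            n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
            chosen = [idx[p] for p in perm]
            train_idx.extend(chosen[:n_train])
            val_idx.extend(chosen[n_train:])
    else:
        perm = rng.permutation(len(dataset))
        n_train = int(math.floor(spec.train_fraction * len(dataset) + 0.5))
        train_idx = list(perm[:n_train])
        val_idx = list(perm[n_train:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(val_idx))


def resize(image: ImageRecord, side: int) -> ImageRecord:
    """Bilinear resize to ``side x side`` (224 for VGG presets, 124 for ResNet50)."""
    if side < 1:
        raise ValidationError("resize side must be >= 1")
    h, w = image.pixels.shape[:2]
    if (h, w) == (side, side):
        return image.copy()
    img = Image.fromarray(image.pixels, mode="RGB").resize((side, side), Image.BILINEAR)
    return ImageRecord(np.asarray(img, dtype=np.uint8), image.label,
                       image.source_id, image.transform_chain)


def _chain_to_str(chain: tuple[TransformSpec, ...]) -> str:
    return "|".join(spec.describe() for spec in chain)


def _parse_value(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def parse_chain(text: str) -> tuple[TransformSpec, ...]:
    """Parse a manifest ``transform_chain`` column back into TransformSpecs."""
    if not text:
        return ()
    specs = []
    for token in text.split("|"):
        name, _, inner = token.partition("(")
        inner = inner.rstrip(")")
        body, _, seed_part = inner.partition(";seed=")
        params = {}
        if body:
            for kv in body.split(","):
                k, _, v = kv.partition("=")
                params[k] = _parse_value(v)
        seed = int(seed_part) if seed_part else None
        specs.append(TransformSpec(name, params, seed))
    return tuple(specs)


def write_dataset(dataset: LabeledDataset, path: str | Path,
                  overwrite: bool = False) -> Path:
    """Write PNG class folders plus a ``manifest.csv``; returns the manifest path.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  PNG keeps the round trip through
    :func:`load_image_folder` pixel-exact.
    """
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise ValidationError(
            f"output directory {root} is not empty (pass overwrite=True to replace)")
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    counters: dict[str, int] = {}
    with manifest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "class", "source_id", "transform_chain", "seed"])
        for rec in dataset.records:
            (root / rec.label).mkdir(exist_ok=True)
            n = counters.get(rec.label, 0)
            counters[rec.label] = n + 1
            fname = f"{rec.label}/{n:05d}.png"
            Image.fromarray(rec.pixels, mode="RGB").save(root / fname)
            seeds = ";".join(str(s.rng_seed) for s in rec.transform_chain
                             if s.rng_seed is not None)
            writer.writerow([fname, rec.label, rec.source_id,
                             _chain_to_str(rec.transform_chain), seeds])
    return manifest
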