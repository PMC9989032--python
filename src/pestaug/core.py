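"""Domain types shared by every module and the label-preservation contract.

The central contract of manipulation-based augmentation is that a transform
``f`` maps a labeled image ``(x, y)`` to ``(f(x), y)``: the pixel raster
changes, the class label never does.  Every type here enforces the 8-bit RGB
raster invariant (3 channels, integer intensities in [0, 255]) and carries
provenance, so an augmented image always knows which source image it came
from and which chain of transforms produced it.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "ImageRecord",
    "LabeledDataset",
    "TransformSpec",
    "REGISTERED_TRANSFORMS",
    "RegistrationError",
    "ValidationError",
    "apply_transform",
    "register_transform",
    "quantize_u8",
    "substream",
]


class ValidationError(ValueError):
    """A parameter or input violates its documented domain."""


class RegistrationError(KeyError):
    """An unknown transform name was requested."""


def quantize_u8(pixels: np.ndarray) -> np.ndarray:
    """Quantize a float raster to uint8: round half away from zero, clip to [0, 255].

    A single quantization rule shared by every transform keeps outputs
    bit-reproducible across runs and platforms.
    """
    x = np.asarray(pixels, dtype=np.float64)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def _source_key(source_id: str) -> int:
    return zlib.crc32(source_id.encode("utf-8"))


def substream(master_seed: int, source_id: str, index: int) -> np.random.Generator:
    """Independent RNG substream for one (source image, transform index) pair.

    A master seed spawns one stream per (source_id, index), so augmentation
    results do not depend on the order in which images are processed.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(_source_key(source_id), int(index)))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class TransformSpec:
    """One atomic transform application: a registered name, its parameters, a seed."""

    name: str
    params: Mapping[str, Any] = field(default_factory=dict)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))

    def describe(self) -> str:
        inner = ",".join(f"{k}={_fmt_param(v)}" for k, v in sorted(self.params.items()))
        seed = "" if self.rng_seed is None else f";seed={self.rng_seed}"
        return f"{self.name}({inner}{seed})"


def _fmt_param(v: Any) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    if isinstance(v, ImageRecord):
        return f"<{v.source_id}>"
    return str(v)


@dataclass(frozen=True)
class ImageRecord:
    """One labeled 8-bit RGB raster with provenance.

    ``source_id`` identifies the originating raw image; ``transform_chain``
    is the append-only sequence of transforms applied to reach this record.
    An untransformed record has an empty chain.
    """

    pixels: np.ndarray
    label: str
    source_id: str
    transform_chain: tuple[TransformSpec, ...] = ()

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"pixels must be (H, W, 3); got shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValidationError("pixels must be integer-typed uint8")
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def evolve(self, pixels: np.ndarray, spec: TransformSpec) -> "ImageRecord":
        """New record with transformed pixels and the spec appended to the chain."""
        return ImageRecord(
            pixels=np.ascontiguousarray(pixels),
            label=self.label,
            source_id=self.source_id,
            transform_chain=self.transform_chain + (spec,),
        )

    def copy(self) -> "ImageRecord":
        return replace(self, pixels=self.pixels.copy())


@dataclass
class LabeledDataset:
    """Ordered collection of ImageRecords over a fixed class set."""

    records: list[ImageRecord]
    classes: list[str]

    def __post_init__(self) -> None:
        known = set(self.classes)
        for rec in self.records:
            if rec.label not in known:
                raise ValidationError(
                    f"record label {rec.label!r} is not in the class set {self.classes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = Counter(rec.label for rec in self.records)
        return {c: counts.get(c, 0) for c in self.classes}

    def by_class(self, label: str) -> list[ImageRecord]:
        if label not in self.classes:
            raise ValidationError(f"unknown class {label!r}")
        return [rec for rec in self.records if rec.label == label]

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices], list(self.classes))

    def source_ids(self) -> set[str]:
        return {rec.source_id for rec in self.records}


# ---------------------------------------------------------------------------
# Transform registry

_REGISTRY: dict[str, Callable[..., ImageRecord]] = {}

#: Names every conforming TransformSpec may carry.
REGISTERED_TRANSFORMS: frozenset[str] = frozenset({
    "rotate", "flip_h", "flip_v", "gaussian_noise", "hist_equalize",
    "scale_in", "scale_out", "mixup", "pca_augment",
})


def register_transform(name: str, fn: Callable[..., ImageRecord]) -> None:
    if name not in REGISTERED_TRANSFORMS:
        raise RegistrationError(f"{name!r} is not a registered transform name")
    _REGISTRY[name] = fn


def apply_transform(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    """Apply one registered transform; the output keeps the input's label.

    Raises
    ------
    RegistrationError
        if ``spec.name`` is not a registered transform.
    ValidationError
        if a parameter lies outside its documented domain.
    """
    if spec.name not in REGISTERED_TRANSFORMS or spec.name not in _REGISTRY:
        raise RegistrationError(f"unknown transform {spec.name!r}")
    out = _REGISTRY[spec.name](image, spec)
    if out.label != image.label:  # defensive: the Eq.-style contract
        raise ValidationError("transform altered the class label")
    return out
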