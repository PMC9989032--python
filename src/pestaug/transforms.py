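"""Atomic label-preserving image manipulations.

Eight operators cover the manipulation families used for pest-image
augmentation: center rotation, horizontal/vertical mirroring, additive
Gaussian noise, per-channel histogram equalization, central-crop zoom
(scale-in) and reflect-pad shrink (scale-out), same-class mixup, and
fancy-PCA channel-intensity perturbation.  Every operator returns a new
:class:`~pestaug.core.ImageRecord` with the same label, the same raster
dimensions, intensities quantized back to uint8 by a single shared rounding
rule, and the operation appended to the provenance chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.transform import rotate as _sk_rotate

from .core import (
    ImageRecord,
    LabeledDataset,
    TransformSpec,
    ValidationError,
    quantize_u8,
    register_transform,
    substream,
)

__all__ = [
    "RotationSpec", "NoiseSpec", "MixupSpec", "PCASpec", "ScaleSpec",
    "rotate", "flip", "gaussian_noise", "hist_equalize",
    "scale_in", "scale_out", "mixup", "pca_augment",
]


# ---------------------------------------------------------------------------
# Parameter specs

@dataclass(frozen=True)
class RotationSpec:
    """Center rotation by ``theta`` degrees (counterclockwise positive)."""

    theta: float
    interpolation: str = "bilinear"   # {nearest | bilinear}
    fill: str = "reflect"             # {reflect | constant}
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValidationError("rotation angle must be finite")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValidationError(f"unknown interpolation {self.interpolation!r}")
        if self.fill not in ("reflect", "constant"):
            raise ValidationError(f"unknown fill mode {self.fill!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian noise on the 0–255 intensity scale."""

    sigma: float = 10.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")


@dataclass(frozen=True)
class MixupSpec:
    """Convex combination of two same-class images with weight ``lambda_weight``."""

    lambda_weight: float = 0.2
    partner_policy: str = "same_class_random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValidationError("mixup weight must lie in [0, 1]")


@dataclass(frozen=True)
class PCASpec:
    """Fancy-PCA intensity perturbation along the channel principal components.

    ``variance_threshold`` selects k = the smallest component count whose
    cumulative explained variance reaches the threshold; ``alpha_sigma``
    scales the per-component Gaussian coefficients (sd = alpha_sigma * λ_j).
    """

    variance_threshold: float = 0.95
    alpha_sigma: float = 0.1
    working_side: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValidationError("variance threshold must lie in (0, 1]")
        if self.alpha_sigma < 0:
            raise ValidationError("alpha_sigma must be >= 0")


@dataclass(frozen=True)
class ScaleSpec:
    """Central-crop zoom: crop side = original side / zoom, resized back."""

    zoom: float = 1.25

    def __post_init__(self) -> None:
        if self.zoom < 1.0:
            raise ValidationError("zoom factor must be >= 1")


# ---------------------------------------------------------------------------
# Helpers

def _resize_u8(pixels: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize of a uint8 raster via Pillow (deterministic)."""
    img = Image.fromarray(pixels, mode="RGB")
    return np.asarray(img.resize((width, height), Image.BILINEAR))


# ---------------------------------------------------------------------------
# Operators

def rotate(image: ImageRecord, spec: RotationSpec | float,
           rng_seed: int | None = None) -> ImageRecord:
    """Rotate about the raster center, keeping the canvas size.

    Angles are reduced modulo 360.  Multiples of 90 degrees on square
    rasters are exact pixel permutations; other angles interpolate
    (nearest or bilinear) with out-of-canvas regions filled per the spec.
    """
    if not isinstance(spec, RotationSpec):
        spec = RotationSpec(theta=float(spec))
    theta = spec.theta % 360.0
    px = image.pixels
    h, w = px.shape[:2]
    if theta % 90.0 == 0.0 and (h == w or theta % 180.0 == 0.0):
        out = np.rot90(px, k=int(theta // 90))
    else:
        order = 0 if spec.interpolation == "nearest" else 1
        mode = "reflect" if spec.fill == "reflect" else "constant"
        rotated = _sk_rotate(px.astype(np.float64), theta, resize=False,
                             order=order, mode=mode, cval=spec.fill_value,
                             preserve_range=True)
        out = quantize_u8(rotated)
    chain = TransformSpec("rotate", {"theta": round(theta, 6),
                                     "interpolation": spec.interpolation,
                                     "fill": spec.fill}, rng_seed)
    return image.evolve(out, chain)


def flip(image: ImageRecord, axis: str) -> ImageRecord:
    """Mirror across the named axis: ``horizontal`` (left-right) or ``vertical``."""
    if axis == "horizontal":
        out = image.pixels[:, ::-1]
        name = "flip_h"
    elif axis == "vertical":
        out = image.pixels[::-1, :]
        name = "flip_v"
    else:
        raise ValidationError(f"unknown flip axis {axis!r}")
    return image.evolve(out, TransformSpec(name, {}))


def gaussian_noise(image: ImageRecord, spec: NoiseSpec,
                   rng: np.random.Generator | int) -> ImageRecord:
    """Add per-pixel, per-channel independent Gaussian noise, then clip/round."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng
    noisy = image.pixels.astype(np.float64)
    noisy += gen.normal(spec.mean, spec.sigma, size=image.pixels.shape)
    chain = TransformSpec("gaussian_noise",
                          {"sigma": spec.sigma, "mean": spec.mean},
                          None if seed is None else int(seed))
    return image.evolve(quantize_u8(noisy), chain)


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = channel.size
    cdf_min = int(cdf[np.nonzero(hist)[0][0]])
    if n == cdf_min:           # constant channel: the map is degenerate
        return channel.copy()
    lut_float = (cdf - cdf_min) / (n - cdf_min) * 255.0
    lut = quantize_u8(lut_float)
    return lut[channel]


def hist_equalize(image: ImageRecord) -> ImageRecord:
    """Per-channel cumulative-histogram equalization.

    Each channel is remapped independently by
    ``out(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255)``; the map is
    monotone non-decreasing per channel, and a constant channel is returned
    unchanged.
    """
    out = np.stack([_equalize_channel(image.pixels[..., c]) for c in range(3)],
                   axis=-1)
    return image.evolve(out, TransformSpec("hist_equalize", {}))


def scale_in(image: ImageRecord, spec: ScaleSpec | float) -> ImageRecord:
    """Zoom in: central crop of side ``floor(side / zoom)``, resized back up."""
    if not isinstance(spec, ScaleSpec):
        spec = ScaleSpec(zoom=float(spec))
    h, w = image.pixels.shape[:2]
    chain = TransformSpec("scale_in", {"zoom": spec.zoom})
    if spec.zoom == 1.0:
        return image.evolve(image.pixels.copy(), chain)
    ch, cw = int(h // spec.zoom), int(w // spec.zoom)
    if ch < 1 or cw < 1:
        raise ValidationError(f"zoom {spec.zoom} crops below one pixel")
    top, left = (h - ch) // 2, (w - cw) // 2
    crop = image.pixels[top:top + ch, left:left + cw]
    return image.evolve(_resize_u8(crop, w, h), chain)


def scale_out(image: ImageRecord, spec: ScaleSpec | float) -> ImageRecord:
    """Zoom out: reflect-pad to ``side * zoom``, resized back down."""
    if not isinstance(spec, ScaleSpec):
        spec = ScaleSpec(zoom=float(spec))
    h, w = image.pixels.shape[:2]
    chain = TransformSpec("scale_out", {"zoom": spec.zoom})
    if spec.zoom == 1.0:
        return image.evolve(image.pixels.copy(), chain)
    ph = int(round(h * (spec.zoom - 1.0) / 2.0))
    pw = int(round(w * (spec.zoom - 1.0) / 2.0))
    padded = np.pad(image.pixels, ((ph, ph), (pw, pw), (0, 0)), mode="reflect")
    return image.evolve(_resize_u8(padded, w, h), chain)


def mixup(first: ImageRecord, second: ImageRecord,
          spec: MixupSpec | float) -> ImageRecord:
    """Per-pixel convex combination ``λ·first + (1−λ)·second`` of two same-class images.

    The partner is resized to the first image's dimensions when they differ;
    the output carries the shared label.  Cross-class pairs and self-pairing
    are rejected, which is what makes mixup label-preserving here.
    """
    if not isinstance(spec, MixupSpec):
        spec = MixupSpec(lambda_weight=float(spec))
    if first.label != second.label:
        raise ValidationError(
            f"mixup pairs must share a class; got {first.label!r} vs {second.label!r}")
    if first is second or (first.source_id == second.source_id
                           and first.transform_chain == second.transform_chain):
        raise ValidationError("mixup partner must be a different image")
    h, w = first.pixels.shape[:2]
    partner = second.pixels
    if partner.shape[:2] != (h, w):
        partner = _resize_u8(partner, w, h)
    lam = spec.lambda_weight
    mixed = lam * first.pixels.astype(np.float64) + (1.0 - lam) * partner.astype(np.float64)
    chain = TransformSpec("mixup", {"lambda": lam, "partner": second.source_id})
    return first.evolve(quantize_u8(mixed), chain)


def pca_augment(dataset: LabeledDataset, spec: PCASpec,
                master_seed: int) -> LabeledDataset:
    """Fancy-PCA augmentation: one perturbed copy of every image in the dataset.

    The 3x3 covariance of [0, 1]-scaled RGB triples is estimated over the
    whole dataset at a fixed working resolution, eigendecomposed, and the
    smallest k components reaching ``variance_threshold`` cumulative
    explained variance are retained.  Each image receives an intensity shift
    ``255 * P_k @ alpha`` with ``alpha_j ~ Normal(0, alpha_sigma * λ_j)``,
    constant over pixels, applied at native resolution.
    """
    if len(dataset) == 0:
        raise ValidationError("pca_augment requires a non-empty dataset")
    side = spec.working_side
    samples = [
        _resize_u8(rec.pixels, side, side).reshape(-1, 3).astype(np.float64) / 255.0
        for rec in dataset
    ]
    stacked = np.concatenate(samples, axis=0)
    cov = np.cov(stacked, rowvar=False)
    if np.trace(cov) < 1e-12:
        raise ValidationError(
            "degenerate channel covariance (zero variance); cannot fit principal components")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    ratios = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(ratios, spec.variance_threshold - 1e-12) + 1)

    out: list[ImageRecord] = []
    for i, rec in enumerate(dataset):
        rng = substream(master_seed, rec.source_id, i)
        alpha = rng.normal(0.0, spec.alpha_sigma * eigvals[:k])
        shift = 255.0 * (eigvecs[:, :k] @ alpha)
        perturbed = rec.pixels.astype(np.float64) + shift[np.newaxis, np.newaxis, :]
        chain = TransformSpec("pca_augment",
                              {"k": k, "variance_threshold": spec.variance_threshold,
                               "alpha_sigma": spec.alpha_sigma},
                              int(master_seed))
        out.append(rec.evolve(quantize_u8(perturbed), chain))
    return LabeledDataset(out, list(dataset.classes))


def select_k_components(dataset: LabeledDataset, spec: PCASpec) -> int:
    """Number of channel principal components retained at the variance threshold."""
    side = spec.working_side
    stacked = np.concatenate(
        [_resize_u8(r.pixels, side, side).reshape(-1, 3).astype(np.float64) / 255.0
         for r in dataset], axis=0)
    cov = np.cov(stacked, rowvar=False)
    if np.trace(cov) < 1e-12:
        raise ValidationError("degenerate channel covariance (zero variance)")
    eigvals = np.clip(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0, None)
    ratios = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(ratios, spec.variance_threshold - 1e-12) + 1)


# ---------------------------------------------------------------------------
# Registry adapters: dispatch apply_transform(record, TransformSpec) calls

def _adapt_rotate(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    p = dict(spec.params)
    rspec = RotationSpec(theta=float(p.get("theta", 0.0)),
                         interpolation=p.get("interpolation", "bilinear"),
                         fill=p.get("fill", "reflect"),
                         fill_value=p.get("fill_value", 0.0))
    out = rotate(image, rspec, spec.rng_seed)
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_flip_h(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    return image.evolve(image.pixels[:, ::-1], spec)


def _adapt_flip_v(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    return image.evolve(image.pixels[::-1, :], spec)


def _adapt_noise(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    nspec = NoiseSpec(sigma=float(spec.params.get("sigma", 10.0)),
                      mean=float(spec.params.get("mean", 0.0)))
    seed = spec.rng_seed if spec.rng_seed is not None else 0
    out = gaussian_noise(image, nspec, int(seed))
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_equalize(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    out = hist_equalize(image)
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_scale_in(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    out = scale_in(image, float(spec.params.get("zoom", 1.25)))
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_scale_out(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    out = scale_out(image, float(spec.params.get("zoom", 1.25)))
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_mixup(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    partner = spec.params.get("partner")
    if not isinstance(partner, ImageRecord):
        raise ValidationError("mixup via apply_transform needs params['partner'] "
                              "set to the partner ImageRecord")
    out = mixup(image, partner, float(spec.params.get("lambda", 0.2)))
    return ImageRecord(out.pixels, out.label, out.source_id,
                       image.transform_chain + (spec,))


def _adapt_pca(image: ImageRecord, spec: TransformSpec) -> ImageRecord:
    raise ValidationError(
        "pca_augment is a dataset-level transform; call pestaug.transforms.pca_augment")


register_transform("rotate", _adapt_rotate)
register_transform("flip_h", _adapt_flip_h)
register_transform("flip_v", _adapt_flip_v)
register_transform("gaussian_noise", _adapt_noise)
register_transform("hist_equalize", _adapt_equalize)
register_transform("scale_in", _adapt_scale_in)
register_transform("scale_out", _adapt_scale_out)
register_transform("mixup", _adapt_mixup)
register_transform("pca_augment", _adapt_pca)
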