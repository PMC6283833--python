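"""Mask-based two-patch mixing augmentation and the conventional baseline.

The mixing strategy cuts a noise field at zero: pixels where the field is
non-negative form one region, the rest the other.  Two labeled source patches
are then blended through this binary mask, producing an augmented patch whose
per-pixel label grid records which source each pixel came from.  Because the
noise is smooth, the two regions are contiguous, natural-looking shapes
rather than salt-and-pepper speckle, so the blend resembles a real image in
which two texture classes meet along an organic boundary.

The conventional baseline augments a single patch: random up/down and
left/right flips, then additive zero-mean Gaussian noise with standard
deviation equal to one tenth of the patch's own intensity standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .noise import NoiseField, noise_field

__all__ = [
    "ClassLabel",
    "Patch",
    "BinaryMask",
    "AugmentedPatch",
    "field_to_mask",
    "perlin_blend",
    "random_flip",
    "gaussian_augment",
    "make_batch",
]


class ClassLabel(IntEnum):
    """The six lung-texture classes; integer encoding is stable package-wide."""

    NORMAL = 0
    GGO = 1
    CONSOLIDATION = 2
    RO = 3
    EMPHYSEMA = 4
    HONEYCOMBING = 5

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown class name: {name!r}") from None


@dataclass(frozen=True)
class Patch:
    """A 2D intensity patch (HU-like values) with a single class label."""

    pixels: np.ndarray
    label: ClassLabel

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
            raise ValueError("pixels must be 2D with both sides >= 2")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixel intensities must be finite")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "label", ClassLabel(self.label))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean grid splitting a patch into two exhaustive, exclusive regions."""

    region: np.ndarray
    source_seed: int

    def __post_init__(self) -> None:
        r = np.asarray(self.region)
        if r.ndim != 2 or r.dtype != np.bool_:
            raise ValueError("region must be a 2D boolean grid")
        object.__setattr__(self, "region", r)


@dataclass(frozen=True)
class AugmentedPatch:
    """Intensity grid with a per-pixel class-label grid and provenance."""

    pixels: np.ndarray
    labels: np.ndarray
    provenance: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        l = np.asarray(self.labels, dtype=np.int64)
        if p.shape != l.shape:
            raise ValueError("pixels and labels must share shape")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "labels", l)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def field_to_mask(field: NoiseField) -> BinaryMask:
    """Threshold a noise field at zero.

    Pixels with value >= 0 (including exact zeros — the documented tie rule)
    go to the True region, negative pixels to the False region.
    """
    return BinaryMask(region=field.values >= 0.0, source_seed=field.seed)


def perlin_blend(patch_a: Patch, patch_b: Patch, mask: BinaryMask) -> AugmentedPatch:
    """Blend two patches through a binary mask.

    Output pixels come from ``patch_a`` where the mask is True and from
    ``patch_b`` elsewhere; the label grid records the same choice, so every
    output pixel is bit-identical to the source its label names.
    """
    if patch_a.shape != patch_b.shape or patch_a.shape != mask.region.shape:
        raise ValueError(
            f"shape mismatch: a={patch_a.shape}, b={patch_b.shape}, "
            f"mask={mask.region.shape}"
        )
    m = mask.region
    pixels = np.where(m, patch_a.pixels, patch_b.pixels)
    labels = np.where(m, int(patch_a.label), int(patch_b.label))
    return AugmentedPatch(
        pixels=pixels,
        labels=labels,
        provenance=(int(patch_a.label), int(patch_b.label), mask.source_seed),
    )


def _flip(arr: np.ndarray, ud: bool, lr: bool) -> np.ndarray:
    if ud:
        arr = arr[::-1, :]
    if lr:
        arr = arr[:, ::-1]
    return arr.copy()


def random_flip(patch, seed: int):
    """Flip up/down and left/right, each independently with probability 0.5.

    Works on both ``Patch`` and ``AugmentedPatch``; a label grid, if present,
    is flipped identically to the pixels.
    """
    rng = np.random.default_rng(seed)
    ud, lr = rng.random(2) < 0.5
    if isinstance(patch, AugmentedPatch):
        return AugmentedPatch(
            pixels=_flip(patch.pixels, ud, lr),
            labels=_flip(patch.labels, ud, lr),
            provenance=patch.provenance,
        )
    return Patch(pixels=_flip(patch.pixels, ud, lr), label=patch.label)


def gaussian_augment(patch: Patch, seed: int) -> Patch:
    """Add zero-mean Gaussian noise with sigma = std(pixels) / 10.

    The population standard deviation over the patch's own 400 (or H*W)
    pixels is used; a constant patch (sigma 0) is returned unchanged.
    """
    sigma = float(np.std(patch.pixels)) / 10.0
    if sigma == 0.0:
        return patch
    eps = np.random.default_rng(seed).normal(0.0, sigma, size=patch.shape)
    return Patch(pixels=patch.pixels + eps, label=patch.label)


def make_batch(
    pool: Sequence[Patch],
    batch_size: int,
    mode: str = "perlin",
    noise_params: dict | None = None,
    seed: int = 0,
    distinct_classes: bool = False,
) -> list[AugmentedPatch]:
    """Assemble a seeded batch of augmented patches.

    perlin mode: each item draws two patches uniformly from the pool, flips
    each independently, and blends them through a fresh sign mask whose seed
    is derived from ``(seed, item index)``.  conventional mode: each item
    draws one patch, flips it, adds Gaussian noise, and carries a uniform
    label grid.  Item i's randomness comes from ``SeedSequence([seed, i])``,
    so batches are fully reproducible and items are independent.

    ``distinct_classes=True`` resamples the second patch until its class
    differs from the first (off by default: the source study does not state
    that the two classes must differ, and same-class blends are label-level
    identities).
    """
    if len(pool) == 0:
        raise ValueError("pool must be non-empty")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if mode not in ("perlin", "conventional"):
        raise ValueError(f"unknown mode: {mode!r}")
    params = {"scale": 0.1, "octaves": 1}
    params.update(noise_params or {})

    out: list[AugmentedPatch] = []
    for item in range(batch_size):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), item]))
        sub = rng.integers(0, 2**31 - 1, size=8)
        if mode == "perlin":
            ia = int(rng.integers(len(pool)))
            ib = int(rng.integers(len(pool)))
            if distinct_classes:
                tries = 0
                while pool[ib].label == pool[ia].label and tries < 1000:
                    ib = int(rng.integers(len(pool)))
                    tries += 1
            a = random_flip(pool[ia], seed=int(sub[0]))
            b = random_flip(pool[ib], seed=int(sub[1]))
            h, w = a.shape
            mask = field_to_mask(
                noise_field(h, w, scale=params["scale"], seed=int(sub[2]),
                            octaves=params["octaves"])
            )
            out.append(perlin_blend(a, b, mask))
        else:
            idx = int(rng.integers(len(pool)))
            p = random_flip(pool[idx], seed=int(sub[0]))
            p = gaussian_augment(p, seed=int(sub[1]))
            out.append(
                AugmentedPatch(
                    pixels=p.pixels,
                    labels=np.full(p.shape, int(p.label), dtype=np.int64),
                    provenance=(int(p.label), int(p.label), int(sub[1])),
                )
            )
    return out
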