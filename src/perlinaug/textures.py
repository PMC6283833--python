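"""Synthetic six-class texture patches emulating HRCT lung-pattern ROIs.

Real HRCT region-of-interest sets for interstitial lung disease are not
publicly deposited, so this module generates a labeled stand-in with
class-separable texture statistics on a Hounsfield-unit-like scale:

* normal          — aerated parenchyma: low level (~-875 HU), mild speckle.
* GGO             — hazy intermediate attenuation with coarse smooth blobs.
* consolidation   — uniform high attenuation near soft-tissue density.
* RO              — fine bright lines (reticulation) over a raised background.
* emphysema       — parenchyma punched by low-attenuation holes (~-1000 HU).
* honeycombing    — air-filled cysts enclosed by thick soft-tissue walls.

Every patch is deterministic in (spec, seed).  Intensities are clipped to
[-1000, 400] HU, the package's default display/normalization window.  The
class parameterization lives in :data:`DEFAULT_SPECS` and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .augment import ClassLabel, Patch

__all__ = ["TextureSpec", "DEFAULT_SPECS", "generate_patch", "generate_dataset", "HU_RANGE"]

HU_RANGE = (-1000.0, 400.0)

_STRUCTURES = ("none", "coarse_blobs", "fine_lines", "rings", "low_attenuation_holes")


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of one class's synthetic texture."""

    label: ClassLabel
    mean_intensity: float
    speckle_sd: float
    structure: str = "none"
    structure_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure: {self.structure!r}")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")


DEFAULT_SPECS: dict[ClassLabel, TextureSpec] = {
    ClassLabel.NORMAL: TextureSpec(ClassLabel.NORMAL, -875.0, 30.0, "none"),
    ClassLabel.GGO: TextureSpec(ClassLabel.GGO, -550.0, 60.0, "coarse_blobs", 4.0),
    ClassLabel.CONSOLIDATION: TextureSpec(ClassLabel.CONSOLIDATION, 50.0, 40.0, "none"),
    ClassLabel.RO: TextureSpec(ClassLabel.RO, -650.0, 50.0, "fine_lines", 4.0),
    ClassLabel.EMPHYSEMA: TextureSpec(ClassLabel.EMPHYSEMA, -700.0, 40.0, "low_attenuation_holes", 3.0),
    ClassLabel.HONEYCOMBING: TextureSpec(ClassLabel.HONEYCOMBING, -850.0, 40.0, "rings", 4.0),
}


def _structure_component(spec: TextureSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Additive structural element on top of the speckled base level."""
    s = np.zeros((size, size))
    scale = max(spec.structure_scale, 1.0)
    if spec.structure == "none":
        return s
    if spec.structure == "coarse_blobs":
        # smooth random field -> hazy patchiness
        raw = rng.normal(0.0, 1.0, size=(size, size))
        smooth = ndimage.gaussian_filter(raw, sigma=scale / 2.0, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            s = smooth / sd * 80.0
        return s
    yy, xx = np.mgrid[0:size, 0:size]
    if spec.structure == "fine_lines":
        # randomly oriented sinusoidal reticulation, rectified to bright lines
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        wave = np.cos(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / scale + phase)
        s = np.where(wave > 0.55, 280.0, 0.0)
        return s
    if spec.structure == "low_attenuation_holes":
        # destroyed alveolar airspaces: disks pulled toward air density
        n_holes = max(2, int(round(size * size / (12 * scale**2))))
        for _ in range(n_holes):
            cy, cx = rng.uniform(0, size, size=2)
            r = rng.uniform(0.8 * scale, 1.4 * scale)
            hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            s[hole] = -320.0
        return s
    # rings: cystic airspaces with thick soft-tissue walls
    n_rings = max(2, int(round(size * size / (16 * scale**2))))
    for _ in range(n_rings):
        cy, cx = rng.uniform(0, size, size=2)
        r = rng.uniform(0.8 * scale, 1.3 * scale)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        wall = (d2 <= (r + 1.2) ** 2) & (d2 > (r - 1.2) ** 2)
        s[wall] = 700.0
    return s


def generate_patch(spec: TextureSpec, size: int = 20, seed: int = 0) -> Patch:
    """Generate one deterministic labeled patch from a texture spec.

    The speckle component is re-centered to exact zero mean, so for
    ``structure="none"`` the patch mean equals ``mean_intensity`` exactly
    (before the [-1000, 400] HU clip).
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.label), int(seed)]))
    base = np.full((size, size), spec.mean_intensity)
    if spec.speckle_sd > 0:
        speckle = rng.normal(0.0, spec.speckle_sd, size=(size, size))
        base = base + (speckle - speckle.mean())
    base = base + _structure_component(spec, size, rng)
    return Patch(pixels=np.clip(base, *HU_RANGE), label=spec.label)


def generate_dataset(
    n_per_class: int = 100,
    size: int = 20,
    seed: int = 0,
    specs: dict[ClassLabel, TextureSpec] | None = None,
):
    """Generate a stratified dataset: ``n_per_class`` patches per class.

    The default mirrors the study design of 100 regions of interest per class,
    600 in total.  Per-patch seeds are ``master_seed * 100000 + patch index``,
    so datasets from different master seeds are disjoint in practice and every
    patch is individually reproducible.
    """
    from .data import PatchDataset  # local import to avoid a cycle

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    specs = specs or DEFAULT_SPECS
    patches = []
    idx = 0
    for label in ClassLabel:
        spec = specs[label]
        for _ in range(n_per_class):
            patches.append(generate_patch(spec, size=size, seed=int(seed) * 100000 + idx))
            idx += 1
    return PatchDataset(patches=patches, name=f"synthetic-{n_per_class}x6-seed{seed}")
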