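"""Patch collections, stratified splitting, normalization and archive I/O.

An archive is an inspectable directory: 16-bit grayscale PNGs for patch
intensities, optional 8-bit indexed PNGs for per-pixel label grids, and a
``manifest.csv`` (columns ``filename,label,label_mask``) fixing the order.
Intensities are stored through the affine map [-1000, 400] HU -> [0, 65535];
round-trips are exact up to that 16-bit quantization (~0.02 HU).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .augment import AugmentedPatch, ClassLabel, Patch
from .textures import HU_RANGE

__all__ = [
    "PatchDataset",
    "DatasetSplit",
    "stratified_split",
    "normalize",
    "write_archive",
    "read_archive",
    "LABEL_PALETTE",
]

# Class colors for indexed label PNGs, mirroring the usual display scheme
# (dark blue, light blue, cyan, yellow, orange, brown for classes 0..5).
LABEL_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (16, 16, 112),
    1: (96, 144, 224),
    2: (0, 224, 224),
    3: (240, 224, 48),
    4: (240, 144, 32),
    5: (144, 96, 32),
}


@dataclass
class PatchDataset:
    """Ordered collection of same-shape labeled patches."""

    patches: list
    name: str = "dataset"

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.patches}
        if len(shapes) > 1:
            raise ValueError(f"patches must share shape, got {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.patches)

    def __getitem__(self, i):
        return self.patches[i]

    def __iter__(self):
        return iter(self.patches)

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(p.label) for p in self.patches])

    def class_counts(self) -> dict[ClassLabel, int]:
        labels = self.labels
        return {c: int(np.sum(labels == int(c))) for c in ClassLabel}


@dataclass
class DatasetSplit:
    """Disjoint stratified train/test partition of a dataset."""

    train: PatchDataset
    test: PatchDataset
    test_fraction: float
    seed: int


def stratified_split(data: PatchDataset, test_fraction: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Split per class: round(test_fraction * n_class) test members each.

    Membership is a seeded per-class shuffle, deterministic in ``seed``;
    within train and test the original dataset order is preserved.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = data.labels
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for c in ClassLabel:
        members = np.flatnonzero(labels == int(c))
        if members.size == 0:
            continue
        n_test = int(round(test_fraction * members.size))
        if n_test < 1:
            raise ValueError(
                f"class {c.name} has {members.size} members; too few for a "
                f"test fraction of {test_fraction}"
            )
        test_idx.update(rng.permutation(members)[:n_test].tolist())
    train = [p for i, p in enumerate(data.patches) if i not in test_idx]
    test = [p for i, p in enumerate(data.patches) if i in test_idx]
    return DatasetSplit(
        train=PatchDataset(train, name=f"{data.name}-train"),
        test=PatchDataset(test, name=f"{data.name}-test"),
        test_fraction=float(test_fraction),
        seed=int(seed),
    )


def normalize(patch: Patch, window_lo: float = HU_RANGE[0], window_hi: float = HU_RANGE[1]) -> Patch:
    """Affinely map [window_lo, window_hi] to [0, 1], clipping outside."""
    if not window_lo < window_hi:
        raise ValueError("window_lo must be < window_hi")
    scaled = (patch.pixels - window_lo) / (window_hi - window_lo)
    return Patch(pixels=np.clip(scaled, 0.0, 1.0), label=patch.label)


def _hu_to_u16(pixels: np.ndarray) -> np.ndarray:
    lo, hi = HU_RANGE
    return np.round(np.clip((pixels - lo) / (hi - lo), 0, 1) * 65535).astype(np.uint16)


def _u16_to_hu(raw: np.ndarray) -> np.ndarray:
    lo, hi = HU_RANGE
    return raw.astype(np.float64) / 65535.0 * (hi - lo) + lo


def write_label_png(labels: np.ndarray, path: Path) -> None:
    """Write a per-pixel label grid as an 8-bit indexed PNG with the class palette."""
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0] * 768
    for idx, rgb in LABEL_PALETTE.items():
        palette[3 * idx : 3 * idx + 3] = rgb
    img.putpalette(palette)
    img.save(path)


def write_archive(data: PatchDataset, path: str | Path) -> Path:
    """Write a dataset to a directory archive; returns the archive path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(data.patches):
        fname = f"patch_{i:05d}.png"
        Image.fromarray(_hu_to_u16(p.pixels)).save(path / fname)
        if isinstance(p, AugmentedPatch):
            mname = f"patch_{i:05d}_labels.png"
            write_label_png(p.labels, path / mname)
            # record the majority class for the manifest's single-label column
            label = ClassLabel(int(np.bincount(p.labels.ravel(), minlength=6).argmax()))
            rows.append({"filename": fname, "label": label.name, "label_mask": mname})
        else:
            rows.append({"filename": fname, "label": p.label.name, "label_mask": ""})
    pd.DataFrame(rows, columns=["filename", "label", "label_mask"]).to_csv(
        path / "manifest.csv", index=False
    )
    return path


def read_archive(path: str | Path) -> PatchDataset:
    """Read a directory archive written by :func:`write_archive`.

    Malformed manifests, missing image files, and unknown class names are
    reported with the offending record.  An archive whose manifest lists no
    rows yields an empty dataset.
    """
    path = Path(path)
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in archive: {path}")
    df = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    required = {"filename", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {manifest} lacks required columns {sorted(required)}")
    patches = []
    for row in df.itertuples(index=False):
        img_path = path / row.filename
        if not img_path.exists():
            raise FileNotFoundError(
                f"manifest record {row.filename!r} refers to a missing file: {img_path}"
            )
        pixels = _u16_to_hu(np.array(Image.open(img_path), dtype=np.uint16))
        label = ClassLabel.from_name(row.label)
        mask_name = getattr(row, "label_mask", "")
        if mask_name:
            mask_path = path / mask_name
            if not mask_path.exists():
                raise FileNotFoundError(
                    f"manifest record {row.filename!r} refers to a missing "
                    f"label mask: {mask_path}"
                )
            labels = np.array(Image.open(mask_path), dtype=np.int64)
            if labels.shape != pixels.shape:
                raise ValueError(
                    f"label mask {mask_name!r} shape {labels.shape} does not "
                    f"match image shape {pixels.shape}"
                )
            patches.append(AugmentedPatch(pixels=pixels, labels=labels, provenance=(row.filename,)))
        else:
            patches.append(Patch(pixels=pixels, label=label))
    return PatchDataset(patches=patches, name=path.name)
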