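"""Pixel-by-pixel accuracy, per-class tables, paired t-tests, tiled inference.

The headline statistic counts, over every pixel of every test patch, whether
the predicted class equals the reference class:

    accuracy = 100 / (Nx * Ny * N_ROI) * sum_{i,j,k} [pred_ijk == true_ijk]

Per-class accuracies restrict the sum to pixels whose reference label is the
class in question; their pixel-weighted average recovers the overall mean.
Two augmentation strategies are compared with a paired t-test on per-ROI
accuracies, the pairing unit being the identical test patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .augment import AugmentedPatch, ClassLabel, Patch
from .model import FusionNetSmall

__all__ = [
    "EvaluationReport",
    "PairedComparison",
    "pixel_accuracy",
    "per_class_table",
    "paired_t",
    "tile_quantify",
    "IGNORE_LABEL",
]

IGNORE_LABEL = -1  # pixels outside the foreground mask


def _as_grid_list(labels, like_shapes=None):
    """Coerce input into a list of 2D int label grids."""
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        return [labels.astype(np.int64)]
    if isinstance(labels, np.ndarray) and labels.ndim == 3:
        return [g.astype(np.int64) for g in labels]
    out = []
    for i, item in enumerate(labels):
        if isinstance(item, AugmentedPatch):
            out.append(item.labels)
        elif isinstance(item, Patch):
            out.append(np.full(item.shape, int(item.label), dtype=np.int64))
        elif isinstance(item, (int, ClassLabel)):
            if like_shapes is None:
                raise ValueError("scalar labels need reference shapes")
            out.append(np.full(like_shapes[i], int(item), dtype=np.int64))
        else:
            out.append(np.asarray(item, dtype=np.int64))
    return out


def pixel_accuracy(predicted, true) -> float:
    """Fraction of pixels with predicted == true, as a percentage.

    Accepts single 2D grids, 3D stacks, or lists of grids/patches.
    """
    preds = _as_grid_list(predicted)
    shapes = [g.shape for g in preds]
    truths = _as_grid_list(true, like_shapes=shapes)
    if len(preds) != len(truths):
        raise ValueError("predicted and true must pair one-to-one")
    correct = total = 0
    for p, t in zip(preds, truths):
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
        valid = t != IGNORE_LABEL
        correct += int(np.sum((p == t) & valid))
        total += int(valid.sum())
    if total == 0:
        raise ValueError("no labeled pixels to score")
    return 100.0 * correct / total


@dataclass
class EvaluationReport:
    """Per-ROI, per-class and mean pixel accuracies (percent)."""

    per_roi_accuracy: list[float]
    per_class_accuracy: dict[ClassLabel, float | None]
    mean_accuracy: float
    n_rois: int
    patch_dims: tuple[int, int]

    def to_rows(self) -> list[dict]:
        rows = [
            {"class": c.name,
             "accuracy_pct": "undefined" if v is None else round(v, 4)}
            for c, v in self.per_class_accuracy.items()
        ]
        rows.append({"class": "MEAN", "accuracy_pct": round(self.mean_accuracy, 4)})
        return rows


def per_class_table(predictions, truths) -> EvaluationReport:
    """Accuracy per reference class plus the overall pixel-weighted mean.

    ``truths`` may be label grids or single class labels per patch.  A class
    with no reference pixels is reported as undefined (None), never as 0.
    """
    preds = _as_grid_list(predictions)
    shapes = [g.shape for g in preds]
    truths_g = _as_grid_list(truths, like_shapes=shapes)
    if len(preds) != len(truths_g):
        raise ValueError("predictions and truths must pair one-to-one")
    per_roi = [pixel_accuracy(p, t) for p, t in zip(preds, truths_g)]
    p_all = np.concatenate([p.ravel() for p in preds])
    t_all = np.concatenate([t.ravel() for t in truths_g])
    valid = t_all != IGNORE_LABEL
    per_class: dict[ClassLabel, float | None] = {}
    for c in ClassLabel:
        sel = valid & (t_all == int(c))
        per_class[c] = None if not sel.any() else 100.0 * float(np.mean(p_all[sel] == int(c)))
    return EvaluationReport(
        per_roi_accuracy=per_roi,
        per_class_accuracy=per_class,
        mean_accuracy=100.0 * float(np.mean(p_all[valid] == t_all[valid])),
        n_rois=len(preds),
        patch_dims=preds[0].shape if preds else (0, 0),
    )


@dataclass
class PairedComparison:
    """Paired t-test on per-ROI accuracies of two classifiers."""

    accuracies_a: list[float]
    accuracies_b: list[float]
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_t(acc_a, acc_b) -> PairedComparison:
    """Two-sided paired t-test on per-ROI accuracy differences.

    Zero-variance differences are degenerate: identical lists give t = 0,
    p = 1; a constant non-zero difference gives an infinite t with p = 0.
    Both are flagged rather than raised.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D lists with >= 2 pairs")
    d = a - b
    if np.std(d) == 0.0:
        if np.all(d == 0.0):
            return PairedComparison(list(a), list(b), 0.0, 1.0, degenerate=True)
        t = np.inf if d[0] > 0 else -np.inf
        return PairedComparison(list(a), list(b), float(t), 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedComparison(list(a), list(b), float(res.statistic), float(res.pvalue))


def tile_quantify(
    model: FusionNetSmall,
    image: np.ndarray,
    foreground_mask: np.ndarray,
    tile: int = 20,
    stride: int | None = None,
) -> np.ndarray:
    """Sliding-window per-pixel labeling of a whole image.

    Tiles of side ``tile`` are advanced by ``stride`` (default tile // 2) in
    both directions, with extra windows flush against the bottom/right edges
    so every pixel is covered.  Overlapping votes are resolved by summing the
    tiles' softmax probabilities and taking the argmax.  Pixels outside
    ``foreground_mask`` are set to ``IGNORE_LABEL`` and must be excluded from
    any accuracy computation.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(foreground_mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and foreground_mask must share shape")
    H, W = image.shape
    if tile > H or tile > W:
        raise ValueError(f"tile {tile} exceeds image dims {image.shape}")
    if not mask.any():
        raise ValueError("foreground mask is empty")
    stride = tile // 2 if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be >= 1")

    def starts(n: int) -> list[int]:
        s = list(range(0, n - tile + 1, stride))
        if s[-1] != n - tile:
            s.append(n - tile)
        return s

    votes = np.zeros((H, W, model.config.n_classes))
    positions = [(i, j) for i in starts(H) for j in starts(W)]
    batch = np.stack([image[i : i + tile, j : j + tile] for i, j in positions])
    probs = model.predict_probs(batch)
    for (i, j), p in zip(positions, probs):
        votes[i : i + tile, j : j + tile, :] += p
    labels = votes.argmax(axis=-1).astype(np.int64)
    labels[~mask] = IGNORE_LABEL
    return labels
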