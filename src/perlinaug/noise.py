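"""2D simplex (improved Perlin) gradient noise, implemented from scratch.

Simplex noise evaluates gradient noise on a triangular lattice: the input
point is skewed onto a grid of simplices, the three corners of the containing
triangle each contribute a radially attenuated dot product between a
pseudorandom gradient vector and the corner-to-point distance vector, and the
attenuated contributions are summed.  The radial falloff kernel is
``(r^2 - d^2)^4`` with ``r^2 = 0.5``, so each corner's influence vanishes
smoothly at radius ``sqrt(0.5)`` and no interpolation step is needed.

Gradients are drawn from the standard 12-direction set (the eight edge and
four diagonal directions of a cube, projected to 2D), selected through a
seeded 256-entry permutation table.  The summed contribution is scaled by 70,
the conventional normalization for this kernel; empirical extremes over large
samples stay just inside [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermutationTable",
    "NoiseField",
    "build_permutation",
    "simplex2d",
    "noise_field",
]

# Skew/unskew constants for the 2D simplex lattice.
_F2 = 0.5 * (np.sqrt(3.0) - 1.0)
_G2 = (3.0 - np.sqrt(3.0)) / 6.0

# 2D components of the classic 12-gradient set.
_GRAD = np.array(
    [
        (1, 1), (-1, 1), (1, -1), (-1, -1),
        (1, 0), (-1, 0), (1, 0), (-1, 0),
        (0, 1), (0, -1), (0, 1), (0, -1),
    ],
    dtype=np.float64,
)

_SCALE = 70.0  # conventional normalization for the (0.5 - d^2)^4 kernel


@dataclass(frozen=True)
class PermutationTable:
    """Seeded permutation of 0..255, doubled for wrap-free indexing.

    ``entries`` holds the 512-long doubled table; ``entries[:256]`` is the
    permutation proper.  Built via :func:`build_permutation`.
    """

    entries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=np.int64)
        if e.shape != (512,) or not np.array_equal(np.sort(e[:256]), np.arange(256)):
            raise ValueError("entries must be a doubled permutation of 0..255")
        if not np.array_equal(e[:256], e[256:]):
            raise ValueError("entries must repeat the permutation twice")
        object.__setattr__(self, "entries", e)


@dataclass(frozen=True)
class NoiseField:
    """A sampled grid of simplex noise values in [-1, 1]."""

    values: np.ndarray
    scale: float
    seed: int
    octaves: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2D grid")
        if np.abs(v).max(initial=0.0) > 1.0:
            raise ValueError("noise values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)


def build_permutation(seed: int) -> PermutationTable:
    """Build the seeded gradient-selection table.

    The permutation is ``numpy.random.default_rng(seed).permutation(256)``
    (PCG64 Fisher–Yates shuffle); this mapping is part of the package contract
    so that independent re-implementations can reproduce it exactly.
    """
    p = np.random.default_rng(seed).permutation(256)
    return PermutationTable(entries=np.concatenate([p, p]), seed=int(seed))


def simplex2d(x, y, table: PermutationTable):
    """Evaluate 2D simplex noise at (x, y); accepts scalars or arrays.

    Returns values in [-1, 1], continuous in (x, y).  Scalars in, scalar out.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("coordinates must be finite")
    scalar = x.ndim == 0 and y.ndim == 0
    x, y = np.broadcast_arrays(x, y)

    # Skew onto the simplex lattice and find the base corner.
    s = (x + y) * _F2
    i = np.floor(x + s).astype(np.int64)
    j = np.floor(y + s).astype(np.int64)
    t = (i + j) * _G2
    x0 = x - (i - t)
    y0 = y - (j - t)

    # Middle corner: (1,0) in the lower triangle, (0,1) in the upper.
    lower = x0 > y0
    i1 = lower.astype(np.int64)
    j1 = 1 - i1

    x1 = x0 - i1 + _G2
    y1 = y0 - j1 + _G2
    x2 = x0 - 1.0 + 2.0 * _G2
    y2 = y0 - 1.0 + 2.0 * _G2

    perm = table.entries
    ii = i & 255
    jj = j & 255
    gi0 = perm[ii + perm[jj]] % 12
    gi1 = perm[ii + i1 + perm[jj + j1]] % 12
    gi2 = perm[ii + 1 + perm[jj + 1]] % 12

    total = np.zeros_like(x0)
    for gi, xc, yc in ((gi0, x0, y0), (gi1, x1, y1), (gi2, x2, y2)):
        t_c = 0.5 - xc * xc - yc * yc
        g = _GRAD[gi]
        contrib = np.where(
            t_c > 0.0,
            t_c**4 * (g[..., 0] * xc + g[..., 1] * yc),
            0.0,
        )
        total = total + contrib

    out = _SCALE * total
    return float(out) if scalar else out


def noise_field(
    height: int,
    width: int,
    scale: float = 0.1,
    seed: int = 0,
    octaves: int = 1,
) -> NoiseField:
    """Sample an (height, width) grid of simplex noise.

    ``values[i, j] = simplex2d(j * scale, i * scale)``: row index i runs
    top-to-bottom, column j left-to-right.  With ``octaves > 1``, octave o is
    sampled at frequency ``2**o`` and amplitude ``2**-o`` and the sum is
    renormalized by the total amplitude so the [-1, 1] bound is preserved.

    ``scale`` is lattice units per pixel; the default 0.1 puts roughly two
    noise feature periods across a 20-pixel patch, giving the coarse
    two-region sign masks the augmentation stage wants.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if not scale > 0:
        raise ValueError("scale must be > 0")
    if octaves < 1:
        raise ValueError("octaves must be >= 1")

    table = build_permutation(seed)
    jj, ii = np.meshgrid(np.arange(width), np.arange(height))
    x = jj * float(scale)
    y = ii * float(scale)

    total = np.zeros((height, width))
    amp_sum = 0.0
    for o in range(octaves):
        amp = 2.0**-o
        freq = 2.0**o
        total += amp * simplex2d(x * freq, y * freq, table)
        amp_sum += amp
    return NoiseField(values=total / amp_sum, scale=float(scale), seed=int(seed), octaves=int(octaves))
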