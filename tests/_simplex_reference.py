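"""Independent scalar transcription of the published reference 2D simplex
noise algorithm (Perlin's improved noise as popularized in Gustavson's
reference implementation), used as an oracle against the package's vectorized
implementation.  Kept deliberately line-by-line scalar: no numpy broadcasting,
no shared code with perlinaug.noise.
"""

import math

_GRAD3 = (
    (1, 1, 0), (-1, 1, 0), (1, -1, 0), (-1, -1, 0),
    (1, 0, 1), (-1, 0, 1), (1, 0, -1), (-1, 0, -1),
    (0, 1, 1), (0, -1, 1), (0, 1, -1), (0, -1, -1),
)

_F2 = 0.5 * (math.sqrt(3.0) - 1.0)
_G2 = (3.0 - math.sqrt(3.0)) / 6.0


def _fastfloor(x: float) -> int:
    xi = int(x)
    return xi - 1 if x < xi else xi


def _dot2(g, x: float, y: float) -> float:
    return g[0] * x + g[1] * y


def reference_simplex2d(xin: float, yin: float, perm) -> float:
    """perm is a doubled (length-512) permutation of 0..255."""
    s = (xin + yin) * _F2
    i = _fastfloor(xin + s)
    j = _fastfloor(yin + s)
    t = (i + j) * _G2
    X0 = i - t
    Y0 = j - t
    x0 = xin - X0
    y0 = yin - Y0

    if x0 > y0:
        i1, j1 = 1, 0
    else:
        i1, j1 = 0, 1

    x1 = x0 - i1 + _G2
    y1 = y0 - j1 + _G2
    x2 = x0 - 1.0 + 2.0 * _G2
    y2 = y0 - 1.0 + 2.0 * _G2

    ii = i & 255
    jj = j & 255
    gi0 = perm[ii + perm[jj]] % 12
    gi1 = perm[ii + i1 + perm[jj + j1]] % 12
    gi2 = perm[ii + 1 + perm[jj + 1]] % 12

    t0 = 0.5 - x0 * x0 - y0 * y0
    if t0 < 0:
        n0 = 0.0
    else:
        t0 *= t0
        n0 = t0 * t0 * _dot2(_GRAD3[gi0], x0, y0)

    t1 = 0.5 - x1 * x1 - y1 * y1
    if t1 < 0:
        n1 = 0.0
    else:
        t1 *= t1
        n1 = t1 * t1 * _dot2(_GRAD3[gi1], x1, y1)

    t2 = 0.5 - x2 * x2 - y2 * y2
    if t2 < 0:
        n2 = 0.0
    else:
        t2 *= t2
        n2 = t2 * t2 * _dot2(_GRAD3[gi2], x2, y2)

    return 70.0 * (n0 + n1 + n2)
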