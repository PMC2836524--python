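"""Analytic raster fixtures with known fractal dimension.

Shapes whose Hausdorff dimension is known in closed form, used to
calibrate and self-test the estimators: a straight line (D = 1), a filled
square (D = 2), the Sierpinski triangle (D = log 3 / log 2) and the Koch
curve (D = log 4 / log 3).
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import line as _draw_line

__all__ = [
    "straight_line",
    "filled_square",
    "sierpinski",
    "koch_curve",
    "SIERPINSKI_DIMENSION",
    "KOCH_DIMENSION",
]

SIERPINSKI_DIMENSION = math.log(3) / math.log(2)
KOCH_DIMENSION = math.log(4) / math.log(3)


def straight_line(length: int = 512) -> np.ndarray:
    """A horizontal 1-px line of the given length (D = 1)."""
    mask = np.zeros((1, length), dtype=bool)
    mask[0, :] = True
    return mask


def filled_square(side: int = 128) -> np.ndarray:
    """A filled side x side square (D = 2)."""
    return np.ones((side, side), dtype=bool)


def sierpinski(depth: int = 6) -> np.ndarray:
    """Sierpinski-triangle raster of size 2^depth with 3^depth pixels.

    Built by the dyadic substitution S -> [[S, 0], [S, S]]: exactly
    self-similar on the dyadic grid, so box counts at dyadic sizes are
    exactly 3^(depth - k) and the log-log fit is exactly collinear.
    """
    mask = np.ones((1, 1), dtype=bool)
    zero = np.zeros((1, 1), dtype=bool)
    for _ in range(depth):
        mask = np.block([[mask, zero], [mask, mask]])
        zero = np.zeros_like(mask)
    return mask


def koch_curve(depth: int = 5, scale: float = 2.0) -> np.ndarray:
    """Rasterized Koch curve built by recursive third-segment substitution.

    ``scale`` is the pixel length of the smallest segment; depth 5 with
    scale 2 spans 2 * 3^5 = 486 px horizontally.
    """
    span = scale * 3**depth
    pts = _koch_points(complex(0, 0), complex(span, 0), depth)
    xs = np.array([p.real for p in pts])
    ys = np.array([p.imag for p in pts])
    ys -= ys.min()
    h = int(np.ceil(ys.max())) + 2
    w = int(np.ceil(xs.max())) + 2
    mask = np.zeros((h, w), dtype=bool)
    for i in range(len(pts) - 1):
        rr, cc = _draw_line(
            int(round(ys[i])), int(round(xs[i])), int(round(ys[i + 1])), int(round(xs[i + 1]))
        )
        mask[rr, cc] = True
    return mask


def _koch_points(p0: complex, p1: complex, depth: int) -> list[complex]:
    if depth == 0:
        return [p0, p1]
    d = (p1 - p0) / 3.0
    a = p0 + d
    b = p0 + 2 * d
    peak = a + d * complex(math.cos(-math.pi / 3), math.sin(-math.pi / 3))
    out: list[complex] = []
    for q0, q1 in ((p0, a), (a, peak), (peak, b), (b, p1)):
        seg = _koch_points(q0, q1, depth - 1)
        out.extend(seg[:-1])
    out.append(p1)
    return out
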