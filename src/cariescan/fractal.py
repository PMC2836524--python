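"""Fractal-dimension estimation for binary discoloration patterns.

Box counting is the primary estimator: a square grid of side ``s`` is laid
over the pattern, the number of cells N(s) containing any foreground pixel
is counted, and the dimension is the negated slope of the ordinary
least-squares line of log N(s) against log s.  A Minkowski-dilation
("sausage") estimator is provided as an independent cross-check: the
pattern is dilated by disks of growing radius r and the dimension follows
from the scaling of the dilated area, A(r) ~ r^(2-D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BoxCountCurve",
    "box_count",
    "fit_fd",
    "dyadic_box_sizes",
    "estimate_fd",
    "minkowski_fd",
]

R_SQUARED_WARN = 0.95


@dataclass(frozen=True)
class BoxCountCurve:
    """A box-counting curve with its log-log regression summary.

    ``fd`` is the negated slope of log N(s) vs log s; ``low_fit_quality``
    flags curves whose log-log points deviate from a line (r² < 0.95),
    which on real patterns usually signals too few scales or a pattern
    that is not self-similar over the scanned range.
    """

    box_sizes: np.ndarray
    counts: np.ndarray
    fd: float
    r_squared: float
    intercept: float

    @property
    def low_fit_quality(self) -> bool:
        return self.r_squared < R_SQUARED_WARN

    def to_dict(self) -> dict:
        return {
            "box_sizes": [int(s) for s in self.box_sizes],
            "counts": [int(c) for c in self.counts],
            "fd": float(self.fd),
            "r_squared": float(self.r_squared),
            "intercept": float(self.intercept),
        }


def box_count(mask: np.ndarray, box_sizes) -> np.ndarray:
    """Count occupied grid cells at each box size.

    The grid is anchored at element (0, 0) of ``mask``; partial cells at
    the right/bottom edges are counted.  Box sizes may exceed the image
    extent (a thin or tiny pattern is then covered by a single partial
    box, giving N = 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty pattern")
    sizes = np.asarray(box_sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("no box sizes given")
    h, w = mask.shape
    if (sizes < 1).any():
        raise ValueError("box size must be >= 1")
    counts = np.empty(sizes.size, dtype=np.int64)
    for i, s in enumerate(sizes):
        nh = -(-h // s)
        nw = -(-w // s)
        padded = np.zeros((nh * s, nw * s), dtype=bool)
        padded[:h, :w] = mask
        occupied = padded.reshape(nh, s, nw, s).any(axis=(1, 3))
        counts[i] = int(occupied.sum())
    return counts


def fit_fd(box_sizes, counts) -> BoxCountCurve:
    """OLS fit of log N(s) on log s; fd is the negated slope."""
    sizes = np.asarray(box_sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sizes.size != counts.size:
        raise ValueError("box_sizes and counts length mismatch")
    if np.unique(sizes).size < 3:
        raise ValueError("insufficient scales: need >= 3 distinct box sizes")
    if (counts < 1).any():
        raise ValueError("all counts must be >= 1")
    x = np.log(sizes)
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-20 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BoxCountCurve(
        box_sizes=np.asarray(box_sizes, dtype=int),
        counts=np.asarray(counts, dtype=int),
        fd=float(-slope),
        r_squared=float(r2),
        intercept=float(intercept),
    )


def dyadic_box_sizes(max_extent: int) -> np.ndarray:
    """Default size ladder: powers of 2 from 2 up to max(max_extent // 4, 16).

    The floor of 16 guarantees at least four scales for any pattern, so
    small isolated lesions still get a defined (near-zero-slope) fit.
    """
    top = max(max_extent // 4, 16)
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    return np.asarray(sizes, dtype=int)


def estimate_fd(mask: np.ndarray, box_sizes=None) -> BoxCountCurve:
    """Box-counting dimension of a pattern, with bounding-box anchoring.

    The pattern is cropped to its bounding box (grid anchored at the
    pattern's top-left corner, single offset) and counted over a dyadic
    size ladder unless explicit ``box_sizes`` are given.  Deterministic
    for a given mask and ladder.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty pattern")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if box_sizes is None:
        box_sizes = dyadic_box_sizes(max(cropped.shape))
    counts = box_count(cropped, box_sizes)
    return fit_fd(box_sizes, counts)


def minkowski_fd(mask: np.ndarray, radii=(2, 4, 8, 16)) -> float:
    """Minkowski-sausage dimension estimate from dilation-area growth.

    Dilation by a Euclidean disk of radius r is computed exactly via the
    distance transform; the estimate is 1 + slope of log(A(r)/r) against
    log(1/r), which recovers D for sets with A(r) ~ r^(2-D).  Radii should
    sit between the pattern's pixelation scale and its feature size: too
    small and lattice effects dominate, too large and the sausage forgets
    the shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty pattern")
    radii = np.asarray(radii, dtype=float)
    if radii.size < 3:
        raise ValueError("need >= 3 dilation radii")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    pad = int(np.ceil(radii.max())) + 1
    padded = np.pad(mask, pad)
    dist = ndimage.distance_transform_edt(~padded)
    areas = np.array([(dist <= r).sum() for r in radii], dtype=float)
    x = np.log(1.0 / radii)
    y = np.log(areas / radii)
    slope = np.polyfit(x, y, 1)[0]
    return float(1.0 + slope)
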