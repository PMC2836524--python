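"""Synthetic tooth images and feature tables for pipeline validation.

Two generators:

* :func:`generate_tooth_image` renders a stylized occlusal view — a bright
  enamel ellipse on a dark background carrying dark discoloration — with
  exact ground-truth masks.  Discoloration morphology follows lesion
  severity: C0 teeth get a few isolated point blobs, C1 a single fissure
  polyline, C2 a branching fissure tree with widened lesion patches, so
  the fractal dimension of the pattern grows with severity (point → line
  → area).

* :func:`generate_feature_table` draws per-tooth (FD, PA, DD) triples from
  truncated-Gaussian class distributions whose default means/SDs and
  class sizes match the clinical sample the reference discriminants were
  derived from (64 C0, 24 C1, 12 C2 teeth).

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.draw import disk, ellipse, line

from .discriminant import TREATMENT_BY_DIAGNOSIS

__all__ = [
    "ClassParams",
    "FeaturePopulation",
    "DEFAULT_POPULATION",
    "ToothImageSpec",
    "SyntheticTooth",
    "generate_tooth_image",
    "generate_feature_table",
]

# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

#: truncation bounds for each feature (physical validity ranges)
FEATURE_BOUNDS = {"fd": (0.0, 2.5), "pa": (0.0, 1.0), "dd": (0.0, 99.0)}


@dataclass(frozen=True)
class ClassParams:
    """Marginal (mean, SD) of FD, PA, DD and the class size."""

    n: int
    fd: tuple[float, float]
    pa: tuple[float, float]
    dd: tuple[float, float]


@dataclass(frozen=True)
class FeaturePopulation:
    classes: dict[str, ClassParams]

    def __post_init__(self) -> None:
        for label, p in self.classes.items():
            if p.n < 0:
                raise ValueError(f"negative class size for {label}")
            for name in ("fd", "pa", "dd"):
                if getattr(p, name)[1] < 0:
                    raise ValueError(f"negative SD for {label}.{name}")

    def with_sizes(self, n: int) -> "FeaturePopulation":
        """Same distributions with every class resized to n records."""
        return FeaturePopulation({k: replace(p, n=n) for k, p in self.classes.items()})


#: per-severity feature distributions of the clinical reference sample
DEFAULT_POPULATION = FeaturePopulation(
    {
        "C0": ClassParams(n=64, fd=(1.09, 0.16), pa=(0.005, 0.009), dd=(16.9, 15.0)),
        "C1": ClassParams(n=24, fd=(1.34, 0.09), pa=(0.012, 0.008), dd=(45.2, 25.1)),
        "C2": ClassParams(n=12, fd=(1.52, 0.09), pa=(0.051, 0.022), dd=(57.9, 27.7)),
    }
)


def truncated_normal(mean: float, sd: float, bounds: tuple[float, float]):
    """Frozen scipy truncated-normal on the given physical range."""
    lo, hi = bounds
    if sd == 0:
        raise ValueError("SD must be positive for a truncated normal")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def generate_feature_table(
    population: FeaturePopulation = DEFAULT_POPULATION,
    seed: int | None = 0,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a labeled feature table from per-class truncated Gaussians.

    Features are independent within a tooth by default; passing a 3x3
    ``correlation`` matrix couples (fd, pa, dd) through a Gaussian copula
    while preserving the truncated marginals.  Treatment labels follow the
    diagnosis (C0 preventive, C1/C2 operative).
    """
    rng = np.random.default_rng(seed)
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (3, 3):
            raise ValueError("correlation must be a 3x3 matrix over (fd, pa, dd)")
    rows = []
    counter = 0
    for label in sorted(population.classes):
        params = population.classes[label]
        if params.n == 0:
            continue
        dists = {
            name: truncated_normal(*getattr(params, name), FEATURE_BOUNDS[name])
            for name in ("fd", "pa", "dd")
        }
        if correlation is None:
            draws = {name: d.rvs(size=params.n, random_state=rng) for name, d in dists.items()}
        else:
            z = rng.multivariate_normal(np.zeros(3), correlation, size=params.n)
            from scipy.stats import norm

            u = norm.cdf(z)
            draws = {
                name: dists[name].ppf(u[:, j]) for j, name in enumerate(("fd", "pa", "dd"))
            }
        for i in range(params.n):
            counter += 1
            rows.append(
                {
                    "tooth_id": f"T{counter:04d}",
                    "fd": float(draws["fd"][i]),
                    "pa": float(draws["pa"][i]),
                    "dd": float(draws["dd"][i]),
                    "diagnosis": label,
                    "treatment": TREATMENT_BY_DIAGNOSIS[label],
                }
            )
    return pd.DataFrame(rows, columns=["tooth_id", "fd", "pa", "dd", "diagnosis", "treatment"])


# ---------------------------------------------------------------------------
# tooth images
# ---------------------------------------------------------------------------

#: default target PA per severity = clinical class means
DEFAULT_TARGET_PA = {"C0": 0.005, "C1": 0.012, "C2": 0.051}


@dataclass(frozen=True)
class ToothImageSpec:
    """Parameters of one rendered tooth image.

    Intensities are 8-bit levels; the surface is brighter than the
    background and the discoloration darker than the surface, matching
    intraoral photographs of enamel.  ``target_pa`` defaults to the
    severity-class mean PA of the clinical reference sample.
    """

    severity: str = "C1"
    size: int = 256
    surface_axes: tuple[int, int] = (100, 70)
    surface_level: int = 200
    background_level: int = 30
    discoloration_level: int = 60
    target_pa: float | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.severity not in ("C0", "C1", "C2"):
            raise ValueError(f"unknown severity: {self.severity!r}")
        if self.target_pa is not None and not 0.0 < self.target_pa < 1.0:
            raise ValueError("target_pa must lie in (0, 1)")

    @property
    def resolved_target_pa(self) -> float:
        return self.target_pa if self.target_pa is not None else DEFAULT_TARGET_PA[self.severity]


@dataclass(frozen=True)
class SyntheticTooth:
    image: np.ndarray
    surface_mask: np.ndarray
    discoloration_mask: np.ndarray
    severity: str
    pa: float


def generate_tooth_image(spec: ToothImageSpec) -> SyntheticTooth:
    """Render one synthetic occlusal image with exact ground-truth masks.

    A severity-specific skeleton (dots / polyline / branching tree) is
    drawn strictly inside the surface ellipse and then thickened to the
    target discolored-pixel count by thresholding the Euclidean distance
    to the skeleton, which controls PA to within the tie structure of the
    distance transform (well inside 20% relative error).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    cy = cx = n // 2
    ry, rx = spec.surface_axes
    if ry >= cy or rx >= cx:
        raise ValueError("surface ellipse does not fit in the image")
    surface = np.zeros((n, n), dtype=bool)
    rr, cc = ellipse(cy, cx, ry, rx, shape=(n, n))
    surface[rr, cc] = True
    surface_area = int(surface.sum())

    margin = max(6, min(ry, rx) // 8)
    interior = ndimage.binary_erosion(surface, iterations=margin)

    target = spec.resolved_target_pa
    n_target = int(round(target * surface_area))
    if n_target < 1 or n_target > int(interior.sum()):
        raise ValueError("target_pa infeasible for the surface geometry")

    skeleton = _draw_skeleton(spec.severity, interior, rng, (cy, cx), (ry, rx))
    pattern = _grow_to_count(skeleton, interior, n_target, rng)

    img = np.full((n, n), float(spec.background_level))
    img[surface] = spec.surface_level
    img[pattern] = spec.discoloration_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    pa = float(pattern.sum()) / surface_area
    if abs(pa - target) > 0.2 * target:
        raise ValueError("could not realize target_pa within 20% relative error")
    return SyntheticTooth(img, surface, pattern, spec.severity, pa)


def _draw_skeleton(severity, interior, rng, center, axes) -> np.ndarray:
    cy, cx = center
    ry, rx = axes
    skel = np.zeros_like(interior)
    if severity == "C0":
        k = int(rng.integers(2, 5))
        pts = _interior_points(interior, rng, k, min_sep=max(ry, rx) // 2)
        for y, x in pts:
            skel[y, x] = True
    elif severity == "C1":
        pts = _fissure_polyline(rng, center, axes, n_segments=6)
        _draw_polyline(skel, pts, interior)
    else:  # C2: branching tree with widened lesion patches
        pts = _fissure_polyline(rng, center, axes, n_segments=6)
        _draw_polyline(skel, pts, interior)
        n_branch = int(rng.integers(3, 6))
        for _ in range(n_branch):
            i = int(rng.integers(1, len(pts) - 1))
            y0, x0 = pts[i]
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.35, 0.7) * ry
            y1 = int(round(y0 + length * np.sin(ang)))
            x1 = int(round(x0 + length * np.cos(ang)))
            _draw_polyline(skel, [(y0, x0), (y1, x1)], interior)
        for _ in range(int(rng.integers(2, 4))):
            i = int(rng.integers(0, len(pts)))
            rr, cc = disk(pts[i], 3.0, shape=skel.shape)
            keep = interior[rr, cc]
            skel[rr[keep], cc[keep]] = True
    if not skel.any():  # degenerate clip: fall back to the center pixel
        skel[cy, cx] = True
    return skel


def _interior_points(interior, rng, k, min_sep):
    ys, xs = np.nonzero(interior)
    chosen: list[tuple[int, int]] = []
    for _ in range(500):
        if len(chosen) == k:
            break
        j = int(rng.integers(0, len(ys)))
        cand = (int(ys[j]), int(xs[j]))
        if all((cand[0] - y) ** 2 + (cand[1] - x) ** 2 >= min_sep**2 for y, x in chosen):
            chosen.append(cand)
    if not chosen:
        chosen = [(int(ys[0]), int(xs[0]))]
    return chosen


def _fissure_polyline(rng, center, axes, n_segments):
    """A jittered path along the long axis of the occlusal ellipse."""
    cy, cx = center
    ry, rx = axes
    horizontal = rx >= ry
    half = (rx if horizontal else ry) * 0.7
    ts = np.linspace(-half, half, n_segments + 1)
    jitter = rng.normal(0.0, (ry if horizontal else rx) * 0.18, size=ts.size)
    pts = []
    for t, j in zip(ts, jitter):
        if horizontal:
            pts.append((int(round(cy + j)), int(round(cx + t))))
        else:
            pts.append((int(round(cy + t)), int(round(cx + j))))
    return pts


def _draw_polyline(canvas, pts, clip):
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        rr, cc = rr[ok], cc[ok]
        keep = clip[rr, cc]
        canvas[rr[keep], cc[keep]] = True


def _grow_to_count(skeleton, interior, n_target, rng) -> np.ndarray:
    """Thicken the skeleton to exactly n_target pixels inside the interior.

    Thresholds the exact Euclidean distance to the skeleton at the largest
    radius whose interior count stays <= n_target, then tops up with a
    random subset of the next equidistant ring, so the realized pixel
    count hits the target exactly (unless the bare skeleton already
    exceeds it).
    """
    dist = ndimage.distance_transform_edt(~skeleton)
    d_int = np.sort(dist[interior])
    if n_target >= d_int.size:
        return interior.copy()
    rho = d_int[n_target - 1]
    full = interior & (dist <= rho)
    # shrink to the largest complete ring not exceeding the target
    below = interior & (dist < rho)
    n_below = int(below.sum())
    deficit = n_target - n_below
    if deficit <= 0:
        return full
    ring_idx = np.flatnonzero((interior & (dist == rho) & ~below).ravel())
    take = rng.choice(ring_idx, size=min(deficit, ring_idx.size), replace=False)
    out = below.ravel().copy()
    out[take] = True
    return out.reshape(interior.shape)
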