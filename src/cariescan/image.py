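"""Tooth-photograph preprocessing and histogram segmentation.

The imaging front end of the screening pipeline: convert an intraoral
photograph to 8-bit grayscale, isolate the bright occlusal surface from the
dark background, isolate dark pit-and-fissure discoloration from the
surface, and compute the area proportion PA = discolored area / surface
area.  All thresholds are global per image and come either from automatic
between-class-variance (Otsu) maximization on the relevant intensity
histogram or from a manual override.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

__all__ = [
    "MaskResult",
    "SegmentationResult",
    "to_gray8",
    "otsu_threshold",
    "segment_surface",
    "segment_discoloration",
    "compute_segmentation",
    "segment_tooth",
    "load_image",
    "save_mask",
    "load_mask",
]

# ITU-R BT.601 luma weights; they sum to 1 so gray input maps to itself.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class MaskResult:
    """A binary mask together with the intensity threshold that produced it."""

    mask: np.ndarray
    threshold: int

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationResult:
    """Occlusal-surface and discoloration masks with areas and PA."""

    surface_mask: np.ndarray
    discoloration_mask: np.ndarray
    surface_area_px: int
    discoloration_area_px: int
    pa: float
    surface_threshold: int | None = None
    discoloration_threshold: int | None = None


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) or grayscale raster to an 8-bit gray image.

    Luminance uses fixed BT.601 weights; values are linearly mapped to the
    [0, 255] range (float input is interpreted on [0, 1], 16-bit integer
    input on its dtype range) and rounded half-up.  Already-gray 8-bit
    input passes through unchanged.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count: {arr.shape[2]}")
        lum = _rescale_to_8bit(arr) @ _LUMA
    elif arr.ndim == 2:
        lum = _rescale_to_8bit(arr)
    else:
        raise ValueError(f"unsupported image dimensionality: {arr.ndim}")
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64) * 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    return arr.astype(np.float64)


def otsu_threshold(values: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over all 8-bit splits.

    Returns the split point t that maximizes the between-class variance of
    the two classes {intensity <= t} and {intensity > t}; ties resolve to
    the lowest t.  Raises on a single-valued (degenerate) histogram.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty intensity sample")
    hist = np.bincount(values.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("degenerate histogram")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[~valid] = -np.inf
    return int(np.argmax(bcv))


def segment_surface(
    img: np.ndarray,
    method: str = "otsu",
    manual_threshold: int | None = None,
    invert: bool = False,
) -> MaskResult:
    """Isolate the occlusal surface from the image background.

    The surface is assumed brighter than the background (pass
    ``invert=True`` for the opposite polarity): foreground = pixels with
    intensity strictly above the threshold.  Only the largest 8-connected
    component is kept and its interior holes are filled, so dark fissures
    do not punch holes in the surface area.
    """
    img = _check_gray(img)
    t = _select_threshold(img.ravel(), method, manual_threshold)
    raw = (img < t) if invert else (img > t)
    if not raw.any():
        raise ValueError("empty surface mask at selected threshold")
    labels = measure.label(raw, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return MaskResult(mask=mask, threshold=t)


def segment_discoloration(
    img: np.ndarray,
    surface: np.ndarray,
    method: str = "otsu",
    manual_threshold: int | None = None,
) -> MaskResult:
    """Isolate pit-and-fissure discoloration within the occlusal surface.

    Discoloration is darker than the surrounding enamel: foreground =
    surface pixels with intensity strictly below the threshold.  Automatic
    thresholding uses the histogram of surface pixels only; the recorded
    threshold is the Otsu split + 1 so that ``intensity < threshold``
    captures exactly the low class of the split.  An empty mask (no pixel
    below threshold) is valid and yields PA = 0.
    """
    img = _check_gray(img)
    surface = _check_mask(surface, img.shape)
    if not surface.any():
        raise ValueError("empty surface mask")
    if method == "manual":
        t = _select_threshold(None, method, manual_threshold)
    else:
        t = _select_threshold(img[surface], method, manual_threshold) + 1
    mask = surface & (img < t)
    return MaskResult(mask=mask, threshold=t)


def compute_segmentation(
    surface: np.ndarray,
    discoloration: np.ndarray,
    surface_threshold: int | None = None,
    discoloration_threshold: int | None = None,
) -> SegmentationResult:
    """Exact pixel areas and PA = discolored area / surface area."""
    surface = np.asarray(surface, dtype=bool)
    discoloration = np.asarray(discoloration, dtype=bool)
    if discoloration.shape != surface.shape:
        raise ValueError("mask inconsistency: shape mismatch")
    if (discoloration & ~surface).any():
        raise ValueError("mask inconsistency: discoloration pixel outside surface")
    surface_area = int(surface.sum())
    if surface_area == 0:
        raise ValueError("zero surface area")
    disc_area = int(discoloration.sum())
    return SegmentationResult(
        surface_mask=surface,
        discoloration_mask=discoloration,
        surface_area_px=surface_area,
        discoloration_area_px=disc_area,
        pa=disc_area / surface_area,
        surface_threshold=surface_threshold,
        discoloration_threshold=discoloration_threshold,
    )


def segment_tooth(
    img: np.ndarray,
    surface_method: str = "otsu",
    surface_threshold: int | None = None,
    discoloration_method: str = "otsu",
    discoloration_threshold: int | None = None,
    invert: bool = False,
) -> SegmentationResult:
    """Full per-image segmentation: surface, discoloration, areas, PA."""
    surf = segment_surface(img, surface_method, surface_threshold, invert=invert)
    disc = segment_discoloration(img, surf.mask, discoloration_method, discoloration_threshold)
    return compute_segmentation(surf.mask, disc.mask, surf.threshold, disc.threshold)


def _select_threshold(values, method: str, manual_threshold: int | None) -> int:
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires a threshold")
        t = int(manual_threshold)
        if not 0 <= t <= 255:
            raise ValueError("manual threshold must be in [0, 255]")
        return t
    if method == "otsu":
        return otsu_threshold(values)
    raise ValueError(f"unknown threshold method: {method!r}")


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if img.dtype != np.uint8:
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError("grayscale image must be integer-valued; use to_gray8 first")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("grayscale intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def _check_mask(mask: np.ndarray, shape) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError("mask shape does not match image shape")
    return mask


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG photograph and return it as an 8-bit gray image."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    return to_gray8(arr)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG: foreground 0, background 255."""
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, 0, 255).astype(np.uint8)
    Image.fromarray(out).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`save_mask` (foreground 0)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr < 128
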