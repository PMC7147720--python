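"""Lesion segmentation by locally adaptive-threshold binarization.

The grayscale image is normalized to [0, 1]; each pixel's threshold is a
sensitivity-scaled local mean over a window centred there, so the lesion
(darker than the surrounding skin) falls below threshold while the skin
stays above it.  A largest-connected-component + hole-filling postprocess
turns the raw binarization into a usable single-lesion mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import GrayImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LesionMask:
    """Binary raster; 1 marks lesion foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    """window_fraction: local-mean window as a fraction of each image side;
    sensitivity: scales the local mean into the threshold; polarity picks
    whether foreground is darker or brighter than its surroundings."""

    window_fraction: float = 0.5
    sensitivity: float = 0.8
    foreground_polarity: str = "dark"

    def __post_init__(self) -> None:
        if not (0.0 < self.window_fraction <= 1.0):
            raise ValueError("window_fraction must lie in (0, 1]")
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.foreground_polarity not in ("dark", "bright"):
            raise ValueError("foreground_polarity must be 'dark' or 'bright'")

    def window_for(self, shape: tuple[int, int]) -> tuple[int, int]:
        """Odd per-axis window sizes (>= 3) induced by window_fraction."""
        win = tuple(max(3, 2 * int(self.window_fraction * s / 2) + 1) for s in shape)
        if min(win) < 3:
            raise ValueError("degenerate window")
        return win  # type: ignore[return-value]


def adaptive_threshold_map(
    gray: GrayImage, params: AdaptiveThresholdParams | None = None
) -> np.ndarray:
    """Per-pixel threshold = sensitivity x local mean of normalized intensity.

    Returns an array the same size as the image with values in [0, 1].
    """
    params = params or AdaptiveThresholdParams()
    win = params.window_for(gray.pixels.shape)
    norm = gray.pixels.astype(float) / 255.0
    local_mean = ndimage.uniform_filter(norm, size=win, mode="reflect")
    return np.clip(params.sensitivity * local_mean, 0.0, 1.0)


def binarize(gray: GrayImage, thresholds: np.ndarray, polarity: str = "dark") -> LesionMask:
    """Threshold the normalized image against a per-pixel threshold raster."""
    if thresholds.shape != gray.pixels.shape:
        raise ValueError(
            f"threshold raster shape {thresholds.shape} does not match image "
            f"shape {gray.pixels.shape}"
        )
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    norm = gray.pixels.astype(float) / 255.0
    fg = norm < thresholds if polarity == "dark" else norm > thresholds
    return LesionMask(pixels=fg)


def segment_lesion(
    gray: GrayImage, params: AdaptiveThresholdParams | None = None
) -> LesionMask:
    """Adaptive binarization, keep the largest component, fill its holes.

    A uniform image (or any empty binarization) yields an empty mask with a
    logged warning rather than an error.
    """
    params = params or AdaptiveThresholdParams()
    thr = adaptive_threshold_map(gray, params)
    raw = binarize(gray, thr, params.foreground_polarity)
    labeled, n = ndimage.label(raw.pixels)
    if n == 0:
        logger.warning("segment_lesion: empty foreground, returning empty mask")
        return LesionMask(pixels=np.zeros(gray.pixels.shape, dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labeled == largest)
    return LesionMask(pixels=mask)


def crop_to_lesion(gray: GrayImage, mask: LesionMask, margin: float = 0.2) -> GrayImage:
    """Crop the grayscale image to the lesion bounding box plus a margin.

    Centers later feature windows on the lesion.  An empty mask returns the
    image uncropped.
    """
    if not mask.pixels.any():
        return gray
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(margin * (r1 - r0))
    mc = int(margin * (c1 - c0))
    r0, r1 = max(0, r0 - mr), min(gray.pixels.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(gray.pixels.shape[1], c1 + mc)
    if r1 - r0 < 8 or c1 - c0 < 8:
        return gray
    return GrayImage(pixels=gray.pixels[r0:r1, c0:c1])


def dice_overlap(a: LesionMask | np.ndarray, b: LesionMask | np.ndarray) -> float:
    """Dice coefficient between two binary masks (1.0 when both empty)."""
    pa = a.pixels if hasattr(a, "pixels") else np.asarray(a, dtype=bool)
    pb = b.pixels if hasattr(b, "pixels") else np.asarray(b, dtype=bool)
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pa, pb).sum() / denom
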