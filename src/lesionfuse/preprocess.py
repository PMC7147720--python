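"""Image loading, grayscale conversion and resizing.

Every later stage (hair removal, segmentation, feature extraction, the
classifiers) consumes the two container types defined here: an 8-bit RGB
:class:`DermoscopyImage` and an 8-bit single-channel :class:`GrayImage`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from ._util import as_uint8, round_half_away_array

#: ITU-R BT.601 luma weights (R, G, B) — the conventional RGB→gray transform.
BT601_WEIGHTS = (0.2989, 0.5870, 0.1140)

_MIN_SIDE = 8


@dataclass(frozen=True)
class DermoscopyImage:
    """An 8-bit RGB dermoscopy-style raster plus provenance metadata.

    ``pixels`` is an ``(H, W, 3)`` ``uint8`` array; ``source_id`` is an
    opaque identifier (typically the file stem) used to match externally
    produced per-image decisions.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(f"image sides must be >= {_MIN_SIDE} px, got {px.shape[:2]}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit single-channel raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected an (H, W) raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path) -> DermoscopyImage:
    """Load a PNG or JPEG file as a :class:`DermoscopyImage`.

    Grayscale and paletted files are expanded to three identical channels.
    Raises ``FileNotFoundError`` for a missing path and ``ValueError``
    (naming the path) for a file that does not decode as an image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            px = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a decodable image file: {path}") from exc
    except OSError as exc:
        raise ValueError(f"corrupt or truncated image file: {path}") from exc
    return DermoscopyImage(pixels=px, source_id=path.stem)


def save_image(img: DermoscopyImage | GrayImage, path: str | Path) -> None:
    """Write an image (or a gray raster) as PNG/JPEG, by extension."""
    Image.fromarray(img.pixels).save(Path(path))


def to_grayscale(
    img: DermoscopyImage, weights: tuple[float, float, float] = BT601_WEIGHTS
) -> GrayImage:
    """Weighted RGB→luma conversion, rounded half-away-from-zero.

    Default weights are BT.601 (0.2989, 0.5870, 0.1140); a gray triplet
    ``(v, v, v)`` maps back to ``v`` exactly because the weights sum to 1.
    """
    w = np.asarray(weights, dtype=float)
    luma = img.pixels.astype(float) @ w
    return GrayImage(pixels=np.clip(round_half_away_array(luma), 0, 255).astype(np.uint8))


def resize_image(img: DermoscopyImage, out_h: int, out_w: int) -> DermoscopyImage:
    """Bilinear resize to exactly ``(out_h, out_w)`` with clamped intensities."""
    if out_h < _MIN_SIDE or out_w < _MIN_SIDE:
        raise ValueError(f"target dimensions must be >= {_MIN_SIDE}, got ({out_h}, {out_w})")
    res = Image.fromarray(img.pixels).resize((int(out_w), int(out_h)), Image.BILINEAR)
    return DermoscopyImage(pixels=np.asarray(res, dtype=np.uint8), source_id=img.source_id)


def resize_gray(gray: GrayImage, out_h: int, out_w: int) -> GrayImage:
    """Bilinear resize of a single-channel raster."""
    if out_h < _MIN_SIDE or out_w < _MIN_SIDE:
        raise ValueError(f"target dimensions must be >= {_MIN_SIDE}, got ({out_h}, {out_w})")
    res = Image.fromarray(gray.pixels).resize((int(out_w), int(out_h)), Image.BILINEAR)
    return GrayImage(pixels=np.asarray(res, dtype=np.uint8))
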