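"""Histogram-of-oriented-gradients descriptors.

Gradients come from centered differences; each pixel votes its gradient
magnitude into the two orientation bins bracketing its gradient direction
(bilinear interpolation between bin centers); per-cell histograms are
grouped into overlapping blocks that are L2-normalized and concatenated in
row-major block order.  The cell size controls how much shape information
the descriptor encodes — smaller cells, longer vectors; 4x4 cells are the
default operating point for lesion shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import GrayImage

DEFAULT_CELL = (4, 4)


@dataclass(frozen=True)
class HogParams:
    cell_size: tuple[int, int] = DEFAULT_CELL
    block_size: tuple[int, int] = (2, 2)  # in cells
    bins: int = 9
    signed: bool = False
    window_size: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least 2 orientation bins")
        if (
            self.window_size[0] % self.cell_size[0] != 0
            or self.window_size[1] % self.cell_size[1] != 0
        ):
            raise ValueError(
                f"cell size {self.cell_size} must divide window size {self.window_size}"
            )

    @property
    def cells(self) -> tuple[int, int]:
        return (
            self.window_size[0] // self.cell_size[0],
            self.window_size[1] // self.cell_size[1],
        )

    @property
    def blocks(self) -> tuple[int, int]:
        cy, cx = self.cells
        by, bx = self.block_size
        if cy < by or cx < bx:
            raise ValueError("block size exceeds cell grid")
        return (cy - by + 1, cx - bx + 1)

    @property
    def vector_length(self) -> int:
        ny, nx = self.blocks
        by, bx = self.block_size
        return ny * nx * by * bx * self.bins


@dataclass(frozen=True)
class HogVector:
    values: np.ndarray
    params: HogParams

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.params.vector_length:
            raise ValueError(
                f"descriptor length {v.size} != expected {self.params.vector_length}"
            )
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return int(self.values.size)


def cell_histograms(gray: GrayImage, params: HogParams | None = None) -> np.ndarray:
    """Unnormalized per-cell orientation histograms, shape (cy, cx, bins).

    The total histogram mass equals the total gradient magnitude of the
    window (votes are only redistributed between bins, never lost).
    """
    params = params or HogParams()
    px = gray.pixels.astype(float)
    if px.shape != params.window_size:
        raise ValueError(
            f"image shape {px.shape} != window size {params.window_size}; "
            "resize before extraction"
        )
    gy, gx = np.gradient(px)
    mag = np.hypot(gx, gy)
    span = 360.0 if params.signed else 180.0
    ang = np.rad2deg(np.arctan2(gy, gx)) % span
    width = span / params.bins
    pos = ang / width - 0.5
    b0 = np.floor(pos).astype(int) % params.bins
    b1 = (b0 + 1) % params.bins
    w1 = pos - np.floor(pos)
    cy, cx = params.cells
    ch, cw = params.cell_size
    rows = (np.arange(px.shape[0]) // ch)[:, None] * np.ones(px.shape[1], int)
    cols = np.ones((px.shape[0], 1), int) * (np.arange(px.shape[1]) // cw)
    hist = np.zeros((cy, cx, params.bins))
    np.add.at(hist, (rows, cols, b0), mag * (1.0 - w1))
    np.add.at(hist, (rows, cols, b1), mag * w1)
    return hist


def extract_hog(gray: GrayImage, params: HogParams | None = None) -> HogVector:
    """Extract the block-normalized HOG descriptor of a window-sized image."""
    params = params or HogParams()
    hist = cell_histograms(gray, params)
    by, bx = params.block_size
    ny, nx = params.blocks
    eps = 1e-12
    out = np.empty((ny, nx, by * bx * params.bins))
    for i in range(ny):
        for j in range(nx):
            block = hist[i : i + by, j : j + bx].ravel()
            out[i, j] = block / np.sqrt(np.sum(block**2) + eps)
    return HogVector(values=out.ravel(), params=params)


def compare_cell_sizes(
    gray: GrayImage,
    sizes: list[tuple[int, int]],
    base: HogParams | None = None,
) -> list[dict]:
    """Descriptor length for each candidate cell size on a fixed window.

    Rows carry the cell size, the resulting vector length, and whether the
    size is the configured default; lengths strictly decrease as the cell
    grows (fewer cells, shorter descriptor).
    """
    base = base or HogParams()
    rows = []
    for size in sizes:
        p = HogParams(
            cell_size=tuple(size),
            block_size=base.block_size,
            bins=base.bins,
            signed=base.signed,
            window_size=base.window_size,
        )
        vec = extract_hog(gray, p)
        rows.append(
            {
                "cell_size": tuple(size),
                "vector_length": vec.length,
                "is_default": tuple(size) == DEFAULT_CELL,
            }
        )
    return rows
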