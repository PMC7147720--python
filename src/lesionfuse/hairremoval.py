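"""DullRazor-style hair removal.

Dark hairs are located by a generalized grayscale morphological closing
(the maximum, over a bank of oriented line structuring elements, of
``closing(image) - image``), candidate components are kept only if they are
thin/long structures, the hair pixels are replaced by bilinear interpolation
across the stroke, and an adaptive median filter smooths the replaced
pixels.  The same mechanism removes dermatologist pen marks, which share the
dark curvilinear geometry of hair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as gray_closing, skeletonize

from .preprocess import DermoscopyImage, GrayImage, to_grayscale

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HairMask:
    """Binary raster aligned to an image; 1 marks hair pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class HairRemovalParams:
    """Tunables of the detection / verification / replacement chain.

    ``se_lengths`` and ``se_angles`` define the bank of oriented line
    structuring elements; ``detect_threshold`` is the minimum closing
    response (8-bit scale) for a candidate hair pixel; components survive
    verification only if their major axis is at least ``min_length`` px and
    their elongation (major/minor axis ratio) is at least
    ``min_elongation``; ``median_window`` caps the adaptive median window.
    """

    se_lengths: tuple[int, ...] = (9,)
    se_angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    detect_threshold: int = 25
    min_elongation: float = 3.0
    min_length: int = 15
    median_window: int = 7
    max_width: float = 7.0

    def __post_init__(self) -> None:
        if any(l < 3 for l in self.se_lengths):
            raise ValueError("structuring-element lengths must all be >= 3")
        if any(not (0.0 <= a < 180.0) for a in self.se_angles):
            raise ValueError("structuring-element angles must lie in [0, 180)")
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be positive")
        if self.min_elongation <= 1:
            raise ValueError("min_elongation must exceed 1")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if self.max_width <= 0:
            raise ValueError("max_width must be positive")


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Boolean line structuring element of given length through its center."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    # endpoint offsets; rows grow downward so the sign of dr mirrors the angle
    dr = -half * np.sin(theta)
    dc = half * np.cos(theta)
    r0, c0 = int(round(half - dr)), int(round(half - dc))
    r1, c1 = int(round(half + dr)), int(round(half + dc))
    size = length
    fp = np.zeros((size, size), dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    fp[np.clip(rr, 0, size - 1), np.clip(cc, 0, size - 1)] = True
    return fp


def closing_response(gray: GrayImage, params: HairRemovalParams) -> np.ndarray:
    """Generalized grayscale closing response.

    For every pixel: the maximum over the oriented line structuring elements
    of ``closing(gray) - gray``.  Dark thin structures (hairs, pen strokes)
    are filled by at least one crossing orientation, so they respond
    strongly; the response is zero on constant regions and bright features.
    """
    px = gray.pixels
    if max(params.se_lengths) > min(px.shape):
        raise ValueError(
            f"structuring element length {max(params.se_lengths)} exceeds "
            f"image side {min(px.shape)}"
        )
    resp = np.zeros(px.shape, dtype=np.int16)
    for length in params.se_lengths:
        for angle in params.se_angles:
            fp = _line_footprint(length, angle)
            closed = gray_closing(px, fp)
            np.maximum(resp, closed.astype(np.int16) - px.astype(np.int16), out=resp)
    return resp


def verify_hair_structure(mask: HairMask, params: HairRemovalParams) -> HairMask:
    """Keep only thin/long connected components.

    A component survives when its major axis length is at least
    ``min_length`` and it is thin: either its major/minor axis ratio is at
    least ``min_elongation`` (a 1-pixel-wide segment has zero minor axis
    and counts as infinitely elongated), or its mean width — area divided
    by skeleton length — is at most ``max_width`` *and* its skeleton has a
    free end.  The width test keeps networks of crossing hairs, which merge
    into a single component whose global axis ratio is near 1 even though
    every branch is thin; the free-end requirement rejects the closed thin
    ring a large dark blob's boundary leaves behind (its skeleton is a
    loop), so compact structures — disks, squares, blob outlines — fail
    every test.  The output is a subset of the input.
    """
    labeled = cc_label(mask.pixels, connectivity=2)
    keep = np.zeros_like(mask.pixels, dtype=bool)
    for region in regionprops(labeled):
        major = region.axis_major_length
        if major < params.min_length:
            continue
        minor = region.axis_minor_length
        elong = np.inf if minor < 1e-9 else major / minor
        if elong >= params.min_elongation:
            keep[labeled == region.label] = True
            continue
        skel = skeletonize(region.image)
        skel_len = int(skel.sum())
        if skel_len > 0 and region.area / skel_len <= params.max_width and _has_free_end(skel):
            keep[labeled == region.label] = True
    return HairMask(pixels=keep)


def _has_free_end(skel: np.ndarray) -> bool:
    """True if any skeleton pixel has at most one 8-connected neighbour."""
    neighbours = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant")
    return bool(np.any(skel & (neighbours <= 2)))  # self + at most 1 neighbour


def detect_hair_mask(gray: GrayImage, params: HairRemovalParams | None = None) -> HairMask:
    """Threshold the closing response, then verify thin/long structure."""
    params = params or HairRemovalParams()
    raw = closing_response(gray, params) > params.detect_threshold
    return verify_hair_structure(HairMask(pixels=raw), params)


def _principal_direction(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Unit (dr, dc) along the principal axis of a pixel set.

    Ties (isotropic components) break toward horizontal, i.e. along columns.
    """
    r = rows - rows.mean()
    c = cols - cols.mean()
    cov = np.array([[np.mean(r * r), np.mean(r * c)], [np.mean(r * c), np.mean(c * c)]])
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) < 1e-12:
        return 0.0, 1.0
    v = evecs[:, int(np.argmax(evals))]
    n = float(np.hypot(v[0], v[1]))
    return (0.0, 1.0) if n == 0 else (float(v[0] / n), float(v[1] / n))


def _donors_along(
    rows: np.ndarray,
    cols: np.ndarray,
    direction: tuple[float, float],
    masked: np.ndarray,
    max_steps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First unmasked pixel from each (row, col) along +-direction.

    Returns (donor_rows, donor_cols, distances); unresolved entries get
    distance inf.
    """
    h, w = masked.shape
    n = rows.size
    dr, dc = direction
    donor_r = np.full(n, -1, dtype=int)
    donor_c = np.full(n, -1, dtype=int)
    dist = np.full(n, np.inf)
    unresolved = np.ones(n, dtype=bool)
    for t in range(1, max_steps + 1):
        if not unresolved.any():
            break
        rr = np.round(rows + t * dr).astype(int)
        cc = np.round(cols + t * dc).astype(int)
        inb = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        cand = unresolved & inb
        if cand.any():
            free = np.zeros(n, dtype=bool)
            free[cand] = ~masked[rr[cand], cc[cand]]
            hit = cand & free
            donor_r[hit] = rr[hit]
            donor_c[hit] = cc[hit]
            dist[hit] = t
            unresolved &= ~hit
        # walking out of bounds on this side ends the search for those pixels
        unresolved &= inb
    return donor_r, donor_c, dist


def inpaint_bilinear(img: DermoscopyImage, mask: HairMask) -> DermoscopyImage:
    """Replace masked pixels by interpolation across the hair stroke.

    For each connected hair component the local stroke orientation is its
    principal axis; every masked pixel takes the distance-weighted average
    of the two nearest unmasked pixels along the perpendicular line.  When
    only one side yields a donor that donor is used; when neither does, the
    nearest unmasked pixel in the four axis directions is the fallback.
    """
    m = mask.pixels
    if m.shape != img.pixels.shape[:2]:
        raise ValueError("mask dimensions do not match image")
    if not m.any():
        return img
    if m.all():
        raise ValueError("no donor pixels: the mask covers the whole image")
    out = img.pixels.astype(float).copy()
    h, w = m.shape
    max_steps = max(h, w)
    labeled = cc_label(m, connectivity=2)
    for region in regionprops(labeled):
        rows, cols = region.coords[:, 0].astype(float), region.coords[:, 1].astype(float)
        dr, dc = _principal_direction(rows, cols)
        perp = (-dc, dr)
        r1, c1, d1 = _donors_along(rows, cols, perp, m, max_steps)
        r2, c2, d2 = _donors_along(rows, cols, (-perp[0], -perp[1]), m, max_steps)
        ri = region.coords[:, 0]
        ci = region.coords[:, 1]
        both = np.isfinite(d1) & np.isfinite(d2)
        one1 = np.isfinite(d1) & ~np.isfinite(d2)
        one2 = np.isfinite(d2) & ~np.isfinite(d1)
        neither = ~np.isfinite(d1) & ~np.isfinite(d2)
        if both.any():
            w1 = (d2[both] / (d1[both] + d2[both]))[:, None]
            out[ri[both], ci[both]] = (
                w1 * out[r1[both], c1[both]] + (1.0 - w1) * out[r2[both], c2[both]]
            )
        if one1.any():
            out[ri[one1], ci[one1]] = out[r1[one1], c1[one1]]
        if one2.any():
            out[ri[one2], ci[one2]] = out[r2[one2], c2[one2]]
        if neither.any():
            for k in np.flatnonzero(neither):
                out[ri[k], ci[k]] = _axis_fallback(out, m, int(ri[k]), int(ci[k]))
    from ._util import as_uint8

    return DermoscopyImage(pixels=as_uint8(out), source_id=img.source_id)


def _axis_fallback(out: np.ndarray, masked: np.ndarray, r: int, c: int) -> np.ndarray:
    h, w = masked.shape
    best, best_d = None, np.inf
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        rr, cc = r + dr, c + dc
        t = 1
        while 0 <= rr < h and 0 <= cc < w:
            if not masked[rr, cc]:
                if t < best_d:
                    best, best_d = out[rr, cc], t
                break
            rr += dr
            cc += dc
            t += 1
    if best is None:
        raise ValueError("no donor pixels reachable from masked pixel")
    return best


def smooth_replaced(
    img: DermoscopyImage, mask: HairMask, params: HairRemovalParams | None = None
) -> DermoscopyImage:
    """Adaptive median smoothing restricted to masked pixels.

    The window grows from 3 up to ``median_window``; the first window whose
    median lies strictly between its min and max supplies the value, else
    the largest window's median is used.  Unmasked pixels are untouched.
    """
    params = params or HairRemovalParams()
    m = mask.pixels
    if m.shape != img.pixels.shape[:2]:
        raise ValueError("mask dimensions do not match image")
    if not m.any():
        return img
    out = img.pixels.copy()
    sizes = list(range(3, params.median_window + 1, 2))
    for ch in range(3):
        plane = img.pixels[:, :, ch]
        decided = np.zeros(m.shape, dtype=bool)
        acc = np.zeros(m.shape, dtype=np.uint8)
        for i, s in enumerate(sizes):
            med = ndimage.median_filter(plane, size=s, mode="reflect")
            lo = ndimage.minimum_filter(plane, size=s, mode="reflect")
            hi = ndimage.maximum_filter(plane, size=s, mode="reflect")
            ok = (med > lo) & (med < hi)
            take = ok & ~decided if i < len(sizes) - 1 else ~decided
            acc[take] = med[take]
            decided |= take
        out[m, ch] = acc[m]
    return DermoscopyImage(pixels=out, source_id=img.source_id)


def remove_hair(
    img: DermoscopyImage, params: HairRemovalParams | None = None
) -> tuple[DermoscopyImage, HairMask]:
    """Full chain: detect dark thin structures, interpolate, smooth.

    Returns the cleaned image and the mask that was replaced.  Pixels
    outside the mask are never modified.  Very thick hair crossing the
    lesion can leave residue; that is expected behaviour, not an error.
    """
    params = params or HairRemovalParams()
    mask = detect_hair_mask(to_grayscale(img), params)
    if mask.count() == 0:
        return img, mask
    cleaned = inpaint_bilinear(img, mask)
    cleaned = smooth_replaced(cleaned, mask, params)
    logger.debug("remove_hair: replaced %d px (%.2f%% of image)",
                 mask.count(), 100.0 * mask.count() / mask.pixels.size)
    return cleaned, mask
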