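"""Deterministic generator of dermoscopy-like images and ground truth.

The generator emulates the visual regularities dermatologists describe:
lesions are darker blobs on lighter skin; melanomas have more irregular,
more asymmetric borders and heterogeneous pigmentation (dark "islands"),
while common nevi are rounder and uniformly pigmented.  Dark curvilinear
hair strokes and pen-mark-like artifacts cross a configurable fraction of
images.  Every image carries exact ground-truth lesion and hair masks, so
hair-detection recall/precision and segmentation Dice are computable with
no human annotation.

All randomness flows from one root seed through a counter-based substream
per image (``numpy.random.SeedSequence(root, index)``), so image k can be
regenerated without generating images 1..k-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import as_uint8
from .hairremoval import HairMask
from .preprocess import DermoscopyImage, save_image
from .segmentation import LesionMask

#: Default frame, matching dermoscopy camera output (H, W).
DEFAULT_SIZE = (560, 768)

#: Class-conditional parameter ranges.  Melanoma ranges for border
#: irregularity and asymmetry sit strictly above the nevus ranges, and only
#: melanomas get pigment islands; these defaults are frozen — they define
#: the study conditions every property test runs under.
NEVUS_IRREGULARITY = (0.02, 0.08)
MELANOMA_IRREGULARITY = (0.15, 0.30)
NEVUS_ASYMMETRY = (0.00, 0.08)
MELANOMA_ASYMMETRY = (0.15, 0.35)
MELANOMA_ISLANDS = (2, 5)

_LABELS = ("melanoma", "common_nevus")

#: Per-split (melanoma, nevus) counts per dataset profile.
PROFILE_COUNTS = {
    "ph2": {"learning": (27, 43), "validation": (13, 17), "testing": (40, 60)},
    "isic": {"learning": (54, 86), "validation": (26, 34), "testing": (80, 120)},
}


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and pigmentation of one synthetic lesion."""

    label: str
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (semi-axis rows, semi-axis cols)
    border_irregularity: float
    asymmetry: float
    pigment_islands: int
    base_color: tuple[int, int, int]
    skin_color: tuple[int, int, int]
    island_colors: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        if self.label == "common_nevus" and self.pigment_islands != 0:
            raise ValueError("common nevus specs carry no pigment islands")


@dataclass
class DatasetManifest:
    """Rows of (path, label, split) plus the generator seed and counts."""

    rows: pd.DataFrame
    seed: int
    counts: dict
    root: Path | None = None

    def split(self, name: str) -> pd.DataFrame:
        return self.rows[self.rows["split"] == name].reset_index(drop=True)


def random_spec(label: str, size: tuple[int, int], rng: np.random.Generator) -> LesionSpec:
    """Draw a class-conditional lesion spec that fits in the frame."""
    h, w = size
    short = min(h, w)
    r0 = rng.uniform(0.16, 0.24) * short / 2 * 2  # lesion mean radius in px
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    aspect = rng.uniform(0.8, 1.0)
    skin = tuple(int(c + rng.integers(-12, 13)) for c in (208, 172, 150))
    if label == "melanoma":
        irr = rng.uniform(*MELANOMA_IRREGULARITY)
        asym = rng.uniform(*MELANOMA_ASYMMETRY)
        islands = int(rng.integers(MELANOMA_ISLANDS[0], MELANOMA_ISLANDS[1] + 1))
        base = tuple(int(c + rng.integers(-10, 11)) for c in (88, 58, 46))
        icolors = tuple(
            tuple(int(c + rng.integers(-12, 13)) for c in (42, 30, 26)) for _ in range(islands)
        )
    else:
        irr = rng.uniform(*NEVUS_IRREGULARITY)
        asym = rng.uniform(*NEVUS_ASYMMETRY)
        islands = 0
        base = tuple(int(c + rng.integers(-10, 11)) for c in (132, 92, 66))
        icolors = ()
    return LesionSpec(
        label=label,
        center=(cy, cx),
        radii=(r0 * aspect, r0),
        border_irregularity=irr,
        asymmetry=asym,
        pigment_islands=islands,
        base_color=base,
        skin_color=skin,
        island_colors=icolors,
    )


def _radial_profile(theta: np.ndarray, spec: LesionSpec, rng: np.random.Generator) -> np.ndarray:
    """Boundary radius r(theta): noisy, asymmetric ellipse."""
    b, a = spec.radii  # rows, cols semi-axes
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    phase = rng.uniform(0, 2 * np.pi)
    base = base * (1.0 + spec.asymmetry * np.cos(theta - phase))
    noise = np.zeros_like(theta)
    for m in range(3, 9):
        noise += rng.uniform(0.3, 1.0) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    noise /= np.max(np.abs(noise)) + 1e-12
    return base * (1.0 + spec.border_irregularity * noise)


def generate_lesion_image(
    spec: LesionSpec, size: tuple[int, int] = DEFAULT_SIZE, seed: int = 0
) -> tuple[DermoscopyImage, LesionMask, str]:
    """Render one lesion image and its exact ground-truth mask.

    Deterministic for a fixed (spec, size, seed).  Raises if the lesion
    cannot fit inside the frame.
    """
    h, w = size
    cy, cx = spec.center
    reach = max(spec.radii) * (1.0 + spec.asymmetry) * (1.0 + spec.border_irregularity)
    if cy - reach < 0 or cy + reach > h or cx - reach < 0 or cx + reach > w:
        raise ValueError(
            f"lesion (reach {reach:.0f}px from ({cy:.0f},{cx:.0f})) exceeds frame {size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_at = _radial_profile(theta, spec, rng)
    mask = dist <= r_at

    # skin: textured base color with mild vignetting
    img = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        img[:, :, ch] = spec.skin_color[ch] + rng.normal(0.0, 5.0, size=(h, w))
    dmax = np.hypot(h / 2, w / 2)
    vign = 1.0 - 0.12 * (np.hypot(yy - h / 2, xx - w / 2) / dmax) ** 2
    img *= vign[:, :, None]

    # lesion layer: base pigment + heterogeneous islands (melanoma only)
    lesion = np.empty_like(img)
    for ch in range(3):
        lesion[:, :, ch] = spec.base_color[ch] + rng.normal(0.0, 6.0, size=(h, w))
    for color in spec.island_colors:
        ang = rng.uniform(0, 2 * np.pi)
        frac = rng.uniform(0.1, 0.55)
        icy = cy + frac * np.sin(ang) * min(spec.radii)
        icx = cx + frac * np.cos(ang) * min(spec.radii)
        ir = rng.uniform(0.10, 0.22) * min(spec.radii)
        idist = np.hypot(yy - icy, xx - icx)
        ialpha = np.clip(1.0 - idist / ir, 0.0, 1.0) ** 0.7
        for ch in range(3):
            lesion[:, :, ch] = (1 - ialpha) * lesion[:, :, ch] + ialpha * color[ch]

    alpha = ndimage.gaussian_filter(mask.astype(float), 1.5)[:, :, None]
    img = (1.0 - alpha) * img + alpha * lesion
    return (
        DermoscopyImage(pixels=as_uint8(img)),
        LesionMask(pixels=mask),
        spec.label,
    )


def overlay_hair(
    img: DermoscopyImage, n_strokes: int, thickness: int = 2, seed: int = 0
) -> tuple[DermoscopyImage, HairMask]:
    """Draw dark curvilinear hair strokes; return image + exact stroke mask.

    Strokes are quadratic Bezier curves stamped at the requested thickness;
    blending is softened at the stroke edge but the returned mask is the
    exact stamped support.  ``n_strokes = 0`` returns the image unchanged.
    """
    if n_strokes < 0:
        raise ValueError("n_strokes must be >= 0")
    h, w = img.height, img.width
    mask = np.zeros((h, w), dtype=bool)
    if n_strokes == 0:
        return img, HairMask(pixels=mask)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA1)))
    out = img.pixels.astype(float).copy()
    for s in range(n_strokes):
        # endpoints on opposite-ish sides, control point bows the curve
        if rng.random() < 0.5:  # left-to-right stroke
            p0 = np.array([rng.uniform(0, h), rng.uniform(0, w * 0.25)])
            p2 = np.array([rng.uniform(0, h), rng.uniform(w * 0.75, w)])
        else:  # top-to-bottom stroke
            p0 = np.array([rng.uniform(0, h * 0.25), rng.uniform(0, w)])
            p2 = np.array([rng.uniform(h * 0.75, h), rng.uniform(0, w)])
        mid = (p0 + p2) / 2
        bow = rng.uniform(-0.25, 0.25) * np.array([h, w])
        p1 = mid + bow
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr, cc] = True
        if thickness > 1:
            stroke = ndimage.binary_dilation(stroke, structure=np.ones((thickness, thickness)))
        color = np.array([35, 26, 20]) + rng.integers(-8, 9, size=3)
        aa = np.clip(ndimage.gaussian_filter(stroke.astype(float), 0.5) * 1.6, 0.0, 1.0)
        out = (1.0 - aa[:, :, None]) * out + aa[:, :, None] * color[None, None, :]
        mask |= stroke
    return DermoscopyImage(pixels=as_uint8(out), source_id=img.source_id), HairMask(pixels=mask)


def generate_dataset(
    profile: str,
    out_dir: str | Path,
    seed: int = 0,
    hair_fraction: float = 0.3,
    size: tuple[int, int] = DEFAULT_SIZE,
) -> DatasetManifest:
    """Write a full train/validation/test image set plus ground truth.

    Image counts per split follow the chosen profile (the ``isic`` profile
    doubles the ``ph2`` one).  Hair is overlaid on ``hair_fraction`` of
    images.  Alongside every image ``X.png`` sit ``X_lesionmask.png`` and,
    when hairy, ``X_hairmask.png``.  The manifest CSV (path, label, split)
    is byte-identical across runs with the same seed.
    """
    if profile not in PROFILE_COUNTS:
        raise ValueError(f"unknown profile {profile!r}; expected one of {tuple(PROFILE_COUNTS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    k = 0
    for split, (n_me, n_cn) in PROFILE_COUNTS[profile].items():
        for label, n in (("melanoma", n_me), ("common_nevus", n_cn)):
            for i in range(n):
                rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
                spec = random_spec(label, size, rng)
                img, lesion_mask, _ = generate_lesion_image(spec, size, seed=int(rng.integers(2**31)))
                stem = f"{split}_{'me' if label == 'melanoma' else 'cn'}_{i:03d}"
                hairy = rng.random() < hair_fraction
                if hairy:
                    img, hair_mask = overlay_hair(
                        img,
                        n_strokes=int(rng.integers(3, 9)),
                        thickness=int(rng.integers(1, 4)),
                        seed=int(rng.integers(2**31)),
                    )
                    save_image_mask(hair_mask.pixels, out_dir / f"{stem}_hairmask.png")
                img = DermoscopyImage(pixels=img.pixels, source_id=stem)
                save_image(img, out_dir / f"{stem}.png")
                save_image_mask(lesion_mask.pixels, out_dir / f"{stem}_lesionmask.png")
                records.append({"path": f"{stem}.png", "label": label, "split": split})
                k += 1
    rows = pd.DataFrame.from_records(records, columns=["path", "label", "split"])
    rows.to_csv(out_dir / "manifest.csv", index=False)
    return DatasetManifest(rows=rows, seed=seed, counts=PROFILE_COUNTS[profile], root=out_dir)


def save_image_mask(mask: np.ndarray, path: Path) -> None:
    """Persist a binary mask as a 1-bit PNG."""
    from PIL import Image

    Image.fromarray(mask.astype(bool)).save(path, bits=1)


def load_mask(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 0


def mock_cnn_decisions(
    manifest: DatasetManifest, error_rate: float, seed: int = 0
) -> tuple[dict, float]:
    """Simulate an externally trained CNN's per-image decisions.

    Each image's true label is flipped with probability ``error_rate``;
    returns the decision table keyed by image id plus the accuracy actually
    measured on the validation split (the number a fusion weight is built
    from).
    """
    from .classifiers.base import LesionDecision

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC11)))
    table = {}
    val_ok = []
    for _, row in manifest.rows.iterrows():
        stem = Path(row["path"]).stem
        truth = 1 if row["label"] == "melanoma" else 0
        flip = rng.random() < error_rate
        d = truth ^ int(flip)
        score = 0.5 + (0.35 + 0.1 * rng.random()) * (1 if d == 1 else -1)
        table[stem] = LesionDecision(d=d, score=float(np.clip(score, 0.0, 1.0)))
        if row["split"] == "validation":
            val_ok.append(int(d == truth))
    val_acc = float(np.mean(val_ok)) if val_ok else float("nan")
    return table, val_acc
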