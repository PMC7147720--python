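"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: Decimal places used to absorb binary floating-point noise before the
#: presentation rounding (e.g. 0.7 * 4.45 = 3.114999999999999...).
_SNAP_PLACES = 9


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round a scalar half-away-from-zero to ``ndigits`` decimal places.

    The value is first snapped to 9 decimals so that a product whose exact
    decimal value ends in ...5 (but whose float representation falls a few
    ulps short) still rounds away from zero, matching hand arithmetic.
    """
    d = Decimal(float(x)).quantize(Decimal(1).scaleb(-_SNAP_PLACES), rounding=ROUND_HALF_UP)
    q = d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(q)


def round_half_away_array(x: np.ndarray) -> np.ndarray:
    """Elementwise round-half-away-from-zero to the nearest integer."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def as_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(round_half_away_array(np.asarray(x, dtype=float)), 0, 255).astype(np.uint8)
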