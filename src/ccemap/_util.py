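"""Small shared helpers: intensity conversion and decimal rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import numpy as np

__all__ = ["rec601_luma", "round_half_up", "round_ratio_half_up"]


def rec601_luma(pixels: np.ndarray) -> np.ndarray:
    """Rec.601 grayscale luma of an RGB array, rounded to nearest integer.

    Accepts an ``H x W x 3`` array (any integer or float dtype in [0, 255])
    or an already-grayscale ``H x W`` array, which is returned rounded.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return np.rint(arr).astype(np.int64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    luma = (
        0.299 * arr[..., 0].astype(np.float64)
        + 0.587 * arr[..., 1]
        + 0.114 * arr[..., 2]
    )
    return np.rint(luma).astype(np.int64)


def round_half_up(value: float, places: int) -> float:
    """Round a float half-up (0.5 away from zero toward +inf) to `places` decimals."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_ratio_half_up(numerator: int, denominator: int, places: int) -> float:
    """Exact half-up rounding of an integer ratio, free of float representation error."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    frac = Fraction(numerator, denominator)
    q = Decimal(1).scaleb(-places)
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))
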