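"""Sliding-window patch tiling and intensity-based patch exclusion.

A still is tiled into overlapping 128 x 128 windows at a 32-pixel stride,
enumerated left-to-right then top-to-bottom, starting at the upper-left
corner.  Windows use 0-based, half-open coordinates [row, row+128) x
[col, col+128).  Two automatic quality rules then drop uninterpretable
windows before classification:

* **blackout** — strictly more than 1% of the 16,384 window pixels have
  grayscale intensity strictly below 70;
* **overexposed** — strictly more than 5% have intensity strictly above 230.

Both rules read Rec.601 luma by default (the channel is configurable), both
inequalities are strict, and blackout takes precedence when both fire.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import numpy as np
import pandas as pd

from ._util import rec601_luma
from .ingest import EffectiveRegionMask, StillPicture

__all__ = [
    "PatchSpec",
    "ExclusionRule",
    "ExclusionReason",
    "tile_grid",
    "patch_gray_stats",
    "is_excluded",
    "extract_patches",
    "patch_inventory",
    "PATCH_SIZE",
    "STRIDE",
]

PATCH_SIZE = 128
STRIDE = 32


@dataclass(frozen=True, order=True)
class PatchSpec:
    """A half-open square window [row, row+size) x [col, col+size)."""

    row: int
    col: int
    size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0 or self.size < 1:
            raise ValueError(f"invalid patch spec {self!r}")

    @property
    def n_pixels(self) -> int:
        return self.size * self.size

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.size),
            slice(self.col, self.col + self.size),
        )

    def in_bounds(self, height: int, width: int) -> bool:
        return self.row + self.size <= height and self.col + self.size <= width


@dataclass(frozen=True)
class ExclusionRule:
    """Thresholds of the automatic blackout / overexposure patch rejection."""

    low_cut: int = 70
    low_frac: float = 0.01
    high_cut: int = 230
    high_frac: float = 0.05
    channel: str = "luma"  # "luma" | "r" | "g" | "b"

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut <= 255):
            raise ValueError("need 0 <= low_cut < high_cut <= 255")
        if not (0 < self.low_frac < 1 and 0 < self.high_frac < 1):
            raise ValueError("fractions must lie strictly in (0, 1)")
        if self.channel not in ("luma", "r", "g", "b"):
            raise ValueError(f"unknown intensity channel {self.channel!r}")


class ExclusionReason(str, Enum):
    NONE = "none"
    BLACKOUT = "blackout"
    OVEREXPOSED = "overexposed"


def tile_grid(
    height: int,
    width: int,
    patch_size: int = PATCH_SIZE,
    stride: int = STRIDE,
) -> list[PatchSpec]:
    """All fully in-bounds windows on the stride grid, row-major order.

    Per axis there are ``floor((dim - patch_size) / stride) + 1`` offsets when
    ``dim >= patch_size``, else none; a 576-pixel axis with the default
    geometry yields 15 offsets, i.e. 225 windows per still.
    """
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    if height < patch_size or width < patch_size:
        return []
    rows = range(0, height - patch_size + 1, stride)
    cols = range(0, width - patch_size + 1, stride)
    return [PatchSpec(r, c, patch_size) for r in rows for c in cols]


def _intensity(pixels: np.ndarray, channel: str) -> np.ndarray:
    if channel == "luma":
        return rec601_luma(pixels)
    idx = "rgb".index(channel)
    return np.asarray(pixels)[..., idx].astype(np.int64)


def _pixels_of(still: StillPicture | np.ndarray) -> np.ndarray:
    return still.pixels if isinstance(still, StillPicture) else np.asarray(still)


def patch_gray_stats(
    still: StillPicture | np.ndarray,
    spec: PatchSpec,
    rule: ExclusionRule = ExclusionRule(),
) -> tuple[int, int]:
    """Counts of window pixels strictly below `low_cut` / above `high_cut`."""
    px = _pixels_of(still)
    h, w = px.shape[:2]
    if not spec.in_bounds(h, w):
        raise IndexError(f"patch {spec} out of bounds for {h}x{w} still")
    window = _intensity(px[spec.slices()], rule.channel)
    return int((window < rule.low_cut).sum()), int((window > rule.high_cut).sum())


def is_excluded(
    still: StillPicture | np.ndarray,
    spec: PatchSpec,
    rule: ExclusionRule = ExclusionRule(),
) -> tuple[bool, ExclusionReason]:
    """Apply the blackout/overexposure rules to one window.

    Blackout fires iff ``n_low / size**2 > low_frac`` (strictly), overexposure
    iff ``n_high / size**2 > high_frac``; blackout is checked first.  With the
    defaults on a 128 x 128 window the tipping counts are 164 dark and 820
    bright pixels.
    """
    n_low, n_high = patch_gray_stats(still, spec, rule)
    n = spec.n_pixels
    if n_low / n > rule.low_frac:
        return True, ExclusionReason.BLACKOUT
    if n_high / n > rule.high_frac:
        return True, ExclusionReason.OVEREXPOSED
    return False, ExclusionReason.NONE


def extract_patches(
    still: StillPicture | np.ndarray,
    mask: EffectiveRegionMask | None = None,
    rule: ExclusionRule = ExclusionRule(),
    patch_size: int = PATCH_SIZE,
    stride: int = STRIDE,
    min_inside: float = 1.0,
) -> list[PatchSpec]:
    """Eligible windows of a still: on the tile grid, inside the effective
    region, and passing the intensity-exclusion rules, in grid order.

    `min_inside` is the minimum fraction of window pixels that must lie inside
    the mask; the default 1.0 requires the window to sit entirely inside.
    """
    px = _pixels_of(still)
    h, w = px.shape[:2]
    if mask is not None and mask.mask.shape != (h, w):
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match still shape {(h, w)}"
        )
    out = []
    for spec in tile_grid(h, w, patch_size, stride):
        if mask is not None:
            inside = mask.mask[spec.slices()].mean()
            if inside < min_inside:
                continue
        excluded, _ = is_excluded(px, spec, rule)
        if not excluded:
            out.append(spec)
    return out


def patch_inventory(
    still: StillPicture,
    mask: EffectiveRegionMask | None = None,
    rule: ExclusionRule = ExclusionRule(),
) -> pd.DataFrame:
    """Per-window bookkeeping table: still_id, row, col, excluded, reason.

    Windows outside the effective region are reported with reason
    ``outside_mask`` so inventories account for every grid position.
    """
    px = still.pixels
    h, w = px.shape[:2]
    records = []
    for spec in tile_grid(h, w):
        if mask is not None and not mask.mask[spec.slices()].all():
            records.append((still.still_id, spec.row, spec.col, True, "outside_mask"))
            continue
        excluded, reason = is_excluded(px, spec, rule)
        records.append((still.still_id, spec.row, spec.col, excluded, reason.value))
    return pd.DataFrame(
        records, columns=["still_id", "row", "col", "excluded", "reason"]
    )
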