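"""Per-still severity profiles from classified patch grids.

The severity of one still is a geometric statistic of its classified
windows.  With the MES0-labelled windows numbered S1..Sn, ``area0`` is the
pixel count of their union S1 ∪ S2 ∪ ... ∪ Sn, and likewise ``area1``,
``area2``, ``area3`` for MES1-3.  The total is the plain arithmetic sum
``area0 + area1 + area2 + area3`` — per-class unions are computed first and
then summed, so a pixel covered by windows of two different grades
contributes to both class areas.  Severity is expressed as the four
fractions ``areaK / total``; a still whose total area is zero (every window
inadequate or ileal) is excluded and rendered as a blank column downstream.
Inadequate-quality and ileal windows never enter any area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .classify import ClassLabel
from .ingest import Camera, Segment
from .patching import PatchSpec

__all__ = [
    "ClassifiedGrid",
    "SeverityProfile",
    "union_area",
    "class_area",
    "severity_profile",
]

SEVERITY_CLASSES = (
    ClassLabel.MES0,
    ClassLabel.MES1,
    ClassLabel.MES2,
    ClassLabel.MES3,
)


@dataclass
class ClassifiedGrid:
    """Classified windows of one still, plus optional map identity."""

    still_id: str
    items: list[tuple[PatchSpec, ClassLabel]]
    image_height: int
    image_width: int
    camera: Camera | None = None
    segment: Segment | None = None
    index_in_segment: int | None = None

    def __post_init__(self) -> None:
        seen: dict[PatchSpec, ClassLabel] = {}
        for spec, label in self.items:
            if not spec.in_bounds(self.image_height, self.image_width):
                raise ValueError(f"patch {spec} out of bounds in {self.still_id}")
            if spec in seen and seen[spec] != label:
                raise ValueError(
                    f"patch {spec} carries conflicting labels in {self.still_id}"
                )
            seen[spec] = ClassLabel(label)


@dataclass(frozen=True)
class SeverityProfile:
    """%-area severity of one still (or its exclusion marker)."""

    still_id: str
    areas: tuple[int, int, int, int]
    total_area: int
    fractions: tuple[float, float, float, float] | None
    excluded: bool
    camera: Camera | None = None
    segment: Segment | None = None
    index_in_segment: int | None = None

    def __post_init__(self) -> None:
        if self.excluded:
            if self.total_area != 0 or self.fractions is not None:
                raise ValueError("excluded profile must have zero area, no fractions")
        else:
            if self.total_area != sum(self.areas) or self.total_area <= 0:
                raise ValueError("total_area must be the positive sum of areas")
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")


def union_area(
    specs: Iterable[PatchSpec], height: int, width: int
) -> int:
    """Exact pixel count of the union of windows, by boolean-canvas rasterization."""
    canvas = np.zeros((height, width), dtype=bool)
    for spec in specs:
        canvas[spec.slices()] = True
    return int(canvas.sum())


def class_area(grid: ClassifiedGrid, label: ClassLabel) -> int:
    """Pixels covered by the union of all windows carrying `label`.

    Zero when no window has the label; invariant to item order and to
    duplicated (window, label) pairs.
    """
    specs = [spec for spec, lab in grid.items if lab == label]
    if not specs:
        return 0
    return union_area(specs, grid.image_height, grid.image_width)


def severity_profile(grid: ClassifiedGrid) -> SeverityProfile:
    """The %-area severity profile of one classified still.

    ``excluded`` is True exactly when the summed MES0-3 union areas are zero,
    e.g. when every eligible window was graded inadequate or ileal.
    """
    areas = tuple(class_area(grid, label) for label in SEVERITY_CLASSES)
    total = sum(areas)
    if total == 0:
        return SeverityProfile(
            grid.still_id, (0, 0, 0, 0), 0, None, True,
            grid.camera, grid.segment, grid.index_in_segment,
        )
    fractions = tuple(a / total for a in areas)
    return SeverityProfile(
        grid.still_id, areas, total, fractions, False,
        grid.camera, grid.segment, grid.index_in_segment,
    )
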