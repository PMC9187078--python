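"""Loading capsule-endoscopy stills, segment manifests and field-of-view masks.

A second-generation colon capsule (CCE-2) carries a forward and a backward
camera and its examination video is reviewed as 576 x 576-pixel still frames.
The reviewer partitions each video into four anatomical segments (cecum +
ascending colon, transverse colon, descending + sigmoid colon, rectum); this
module takes that partition as a declarative :class:`SegmentManifest` rather
than inferring capsule location, and samples a fixed number of stills per
segment.  Optics leave a roughly circular effective field of view with dark
corners; :func:`estimate_fov_mask` recovers it by flood-filling near-black
regions connected to the image corners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from ._util import rec601_luma

logger = logging.getLogger(__name__)

__all__ = [
    "Camera",
    "Segment",
    "SEGMENT_ORDER",
    "StillPicture",
    "SegmentManifest",
    "ManifestEntry",
    "EffectiveRegionMask",
    "load_still",
    "uniform_sample_indices",
    "extract_stills",
    "estimate_fov_mask",
    "read_manifest",
    "load_mask_file",
]

STANDARD_SIDE = 576  # native CCE-2 still size in pixels


class Camera(str, Enum):
    """Capsule camera: forward-facing (f) or backward-facing (b)."""

    FORWARD = "f"
    BACKWARD = "b"


class Segment(str, Enum):
    """Colorectal segment, in anatomical (oral-to-anal) order."""

    CECUM_ASCENDING = "cecum_ascending"
    TRANSVERSE = "transverse"
    DESCENDING_SIGMOID = "descending_sigmoid"
    RECTUM = "rectum"


SEGMENT_ORDER: dict[Segment, int] = {s: i for i, s in enumerate(Segment)}


@dataclass(frozen=True)
class StillPicture:
    """One still frame with its identity along the colorectum."""

    study_id: str
    camera: Camera
    segment: Segment
    index_in_segment: int
    pixels: np.ndarray  # H x W x 3 uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3:
            raise ValueError(f"still pixels must be H x W x 3, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("still pixel values must lie in [0, 255]")
        if self.index_in_segment < 0:
            raise ValueError("index_in_segment must be >= 0")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def still_id(self) -> str:
        return (
            f"{self.study_id}:{self.camera.value}:"
            f"{self.segment.value}:{self.index_in_segment}"
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class EffectiveRegionMask:
    """Boolean mask of the optically valid field of view (True = inside)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @classmethod
    def all_true(cls, height: int, width: int) -> "EffectiveRegionMask":
        return cls(np.ones((height, width), dtype=bool))


@dataclass(frozen=True)
class ManifestEntry:
    """One manifest row: where the stills of a (camera, segment) come from.

    ``source`` is either a video file, a glob of still images, or a symbolic
    name resolved by the caller; ``start_frame``/``end_frame`` bound the frame
    range (half-open is *not* used here: both ends inclusive, matching how
    reviewers note ranges).
    """

    source: str
    camera: Camera
    segment: Segment
    start_frame: int | None = None
    end_frame: int | None = None


@dataclass
class SegmentManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Each (camera, segment) appears once; frame ranges per source/camera
        do not overlap, and segments are ordered cecum -> rectum."""
        seen: set[tuple[Camera, Segment]] = set()
        by_cam: dict[tuple[str, Camera], list[ManifestEntry]] = {}
        for e in self.entries:
            key = (e.camera, e.segment)
            if key in seen:
                raise ValueError(
                    f"duplicate manifest entry for camera={e.camera.value} "
                    f"segment={e.segment.value}"
                )
            seen.add(key)
            by_cam.setdefault((e.source, e.camera), []).append(e)
        for (_, cam), ents in by_cam.items():
            ranged = [e for e in ents if e.start_frame is not None]
            ranged.sort(key=lambda e: SEGMENT_ORDER[e.segment])
            for a, b in zip(ranged, ranged[1:]):
                if a.end_frame is None or b.start_frame is None:
                    continue
                if b.start_frame <= a.end_frame:
                    raise ValueError(
                        f"overlapping frame ranges for camera {cam.value}: "
                        f"{a.segment.value} ends at {a.end_frame}, "
                        f"{b.segment.value} starts at {b.start_frame}"
                    )


def load_still(
    path: str | Path,
    study_id: str,
    camera: Camera,
    segment: Segment,
    index_in_segment: int,
) -> StillPicture:
    """Load one JPEG/PNG still and attach its identity.

    Non-576x576 inputs are accepted but logged, since downstream patch
    geometry assumes the native capsule frame size.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        px = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    px = np.asarray(px)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    still = StillPicture(study_id, camera, segment, index_in_segment, px)
    h, w = still.shape
    if (h, w) != (STANDARD_SIDE, STANDARD_SIDE):
        logger.warning(
            "still %s is %dx%d, not the native %dx%d", path, h, w,
            STANDARD_SIDE, STANDARD_SIDE,
        )
    return still


def uniform_sample_indices(length: int, n: int) -> list[int]:
    """Indices of `n` frames sampled uniformly from `length` frames.

    Endpoints are always included when ``n >= 2``: index i maps to
    ``round(i * (length - 1) / (n - 1))``.  ``n == 1`` takes the first frame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < n:
        raise ValueError(f"cannot sample {n} frames from a range of length {length}")
    if n == 1:
        return [0]
    return [round(i * (length - 1) / (n - 1)) for i in range(n)]


def extract_stills(
    frames: Sequence[np.ndarray] | np.ndarray,
    entry: ManifestEntry,
    study_id: str,
    n_stills: int = 50,
) -> list[StillPicture]:
    """Sample `n_stills` frames uniformly from a manifest entry's frame range.

    `frames` is any index-able frame source (an ``N x H x W x 3`` array, a list
    of frames, or an open ``imageio`` reader).  Sampling is deterministic and
    order-preserving; the first and last frame of the range are included when
    ``n_stills >= 2``.
    """
    n_frames = len(frames)
    start = entry.start_frame if entry.start_frame is not None else 0
    end = entry.end_frame if entry.end_frame is not None else n_frames - 1
    if not (0 <= start <= end < n_frames):
        raise ValueError(
            f"frame range [{start}, {end}] invalid for a source with "
            f"{n_frames} frames"
        )
    length = end - start + 1
    if length < n_stills:
        raise ValueError(
            f"frame range has only {length} frames, cannot extract {n_stills}"
        )
    out = []
    for i, rel in enumerate(uniform_sample_indices(length, n_stills)):
        px = np.asarray(frames[start + rel])
        out.append(StillPicture(study_id, entry.camera, entry.segment, i, px))
    return out


def estimate_fov_mask(
    still: StillPicture | np.ndarray, corner_threshold: int = 30
) -> EffectiveRegionMask:
    """Estimate the effective (field-of-view) region of a still.

    Near-black pixels (Rec.601 luma < `corner_threshold`) that form connected
    components touching any image corner are taken as the optical vignette and
    masked out; everything else is inside.  Degenerate stills (no dark corner
    component, or everything dark) fall back to an all-true mask — the patch
    intensity-exclusion rules handle uninformative content downstream.
    """
    px = still.pixels if isinstance(still, StillPicture) else np.asarray(still)
    gray = rec601_luma(px)
    h, w = gray.shape
    dark = gray < corner_threshold
    if not dark.any() or dark.all():
        return EffectiveRegionMask.all_true(h, w)
    labels = cc_label(dark, connectivity=2)
    corner_ids = {labels[r, c] for r in (0, h - 1) for c in (0, w - 1)}
    corner_ids.discard(0)
    if not corner_ids:
        return EffectiveRegionMask.all_true(h, w)
    outside = np.isin(labels, sorted(corner_ids))
    return EffectiveRegionMask(~outside)


def read_manifest(path: str | Path) -> SegmentManifest:
    """Read a segment manifest CSV.

    Columns: ``source,camera,segment,start_frame,end_frame``; camera is ``f``
    or ``b``; segment one of the four colorectal segment names; frame columns
    may be empty when `source` is a glob of still files.
    """
    df = pd.read_csv(path, dtype={"source": str, "camera": str, "segment": str})
    required = {"source", "camera", "segment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        start = getattr(row, "start_frame", None)
        end = getattr(row, "end_frame", None)
        entries.append(
            ManifestEntry(
                source=row.source,
                camera=Camera(row.camera),
                segment=Segment(row.segment),
                start_frame=None if pd.isna(start) else int(start),
                end_frame=None if pd.isna(end) else int(end),
            )
        )
    return SegmentManifest(entries)


def load_mask_file(path: str | Path) -> EffectiveRegionMask:
    """Load a user-supplied mask override: single-channel PNG, nonzero = inside."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return EffectiveRegionMask(arr != 0)
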