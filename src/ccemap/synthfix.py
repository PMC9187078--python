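"""Synthetic capsule stills and labeled patch sets with known ground truth.

Clinical capsule video cannot ship with the package, so every pipeline stage
is exercised on generated imagery instead.  Each of the six patch categories
(MES0-3, inadequate quality, ileal mucosa) is painted as a gray vertical
grating with a class-specific spatial frequency and base intensity:

* class *k* uses ``CYCLES[k]`` full cycles per 128 pixels — 4, 8, 12, 16, 20,
  24 — so every aligned 32-pixel block contains an integer number of cycles
  (1..6) and the frequency lands on an exact FFT bin at any window offset;
* class *k* sits on base level ``BASE[k]`` (105..205 in steps of 20), with
  grating amplitude 18 and seeded uniform pixel noise in [-5, 5], keeping all
  texture values inside (70, 230) so a class texture never trips the
  blackout/overexposure rules on its own.

The signature is therefore machine-decodable (see :func:`decode_block`) yet
noisy enough that a trainable classifier has a real, if easy, learning task.
Defect regions are painted at intensity 10 (blackout) or 250 (overexposed),
guaranteed to trigger the corresponding exclusion rule; pixels outside an
optional circular field of view are exactly 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import rec601_luma
from .classify import ClassLabel
from .ingest import Camera, Segment, StillPicture

__all__ = [
    "CYCLES",
    "BASE",
    "AMPLITUDE",
    "NOISE_HALF_RANGE",
    "Rect",
    "LayoutSpec",
    "LabeledPatchSet",
    "StudyBundle",
    "texture_value",
    "paint_texture",
    "decode_block",
    "decode_patch",
    "generate_synthetic_still",
    "generate_labeled_patchset",
    "generate_study",
    "default_profile_script",
    "write_study",
]

# class index -> cycles per 128 px; all multiples of 4 so a 32-px block holds
# an integer cycle count and the |FFT| peak is offset-invariant
CYCLES: tuple[int, ...] = (4, 8, 12, 16, 20, 24)
# class index -> base gray level; spacing 20 >> noise so levels never overlap
BASE: tuple[int, ...] = (105, 125, 145, 165, 185, 205)
AMPLITUDE = 18
NOISE_HALF_RANGE = 5
BLACKOUT_VALUE = 10
OVEREXPOSED_VALUE = 250
_PERIOD = 128  # columns over which CYCLES counts full cycles


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"degenerate rectangle {self}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class LayoutSpec:
    """Declarative description of one synthetic still."""

    side: int = 576
    regions: list[tuple[Rect, ClassLabel]] = field(default_factory=list)
    fov: tuple[int, int, int] | None = None  # (center_row, center_col, radius)
    defects: list[tuple[Rect, str]] = field(default_factory=list)  # blackout|overexposed
    seed: int = 0


@dataclass
class LabeledPatchSet:
    """Patch pixels + labels for one split of a training benchmark."""

    X: np.ndarray  # n x side x side x 3 uint8
    y: np.ndarray  # n int labels 0..5
    split: str  # "train" | "validation"

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")

    def __len__(self) -> int:
        return len(self.X)

    def class_counts(self) -> dict[ClassLabel, int]:
        return {c: int((self.y == c.value).sum()) for c in ClassLabel}


def texture_value(label: ClassLabel, cols: np.ndarray) -> np.ndarray:
    """Noise-free texture intensity of a class at absolute image columns."""
    phase = 2.0 * np.pi * CYCLES[label.value] * np.asarray(cols, dtype=float) / _PERIOD
    return BASE[label.value] + AMPLITUDE * np.sin(phase)


def paint_texture(
    canvas: np.ndarray, rect: Rect, label: ClassLabel
) -> None:
    """Paint a class texture into a grayscale canvas, phase-locked to absolute
    column coordinates so adjacent regions tile seamlessly."""
    cols = np.arange(rect.col0, rect.col1)
    row_vals = texture_value(label, cols)
    canvas[rect.slices()] = np.broadcast_to(
        row_vals, (rect.row1 - rect.row0, len(cols))
    )


def generate_synthetic_still(
    layout: LayoutSpec,
    study_id: str = "synthetic",
    camera: Camera = Camera.FORWARD,
    segment: Segment = Segment.CECUM_ASCENDING,
    index_in_segment: int = 0,
) -> tuple[StillPicture, np.ndarray]:
    """Render one synthetic still and its per-pixel ground-truth label map.

    Returns the still plus an ``H x W`` int8 array holding the class index at
    classifiable pixels and -1 at pixels with no class (outside the field of
    view, or painted as an intensity defect).  Deterministic for a fixed
    layout seed.
    """
    if not layout.regions:
        raise ValueError("layout has no class regions")
    n = layout.side
    canvas = np.full((n, n), -1.0)
    labels = np.full((n, n), -1, dtype=np.int8)
    for rect, label in layout.regions:
        if not isinstance(label, ClassLabel):
            raise ValueError(f"region {rect} carries no valid class label: {label!r}")
        if rect.row1 > n or rect.col1 > n:
            raise ValueError(f"region {rect} exceeds the {n}x{n} frame")
        paint_texture(canvas, rect, label)
        labels[rect.slices()] = label.value

    rows, cols = np.mgrid[0:n, 0:n]
    if layout.fov is not None:
        cr, cc, radius = layout.fov
        inside = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    else:
        inside = np.ones((n, n), dtype=bool)
    if (canvas[inside] < 0).any():
        raise ValueError("class regions do not cover the field of view")

    for rect, kind in layout.defects:
        if kind == "blackout":
            canvas[rect.slices()] = BLACKOUT_VALUE
        elif kind == "overexposed":
            canvas[rect.slices()] = OVEREXPOSED_VALUE
        else:
            raise ValueError(f"unknown defect kind {kind!r}")
        labels[rect.slices()] = -1

    rng = np.random.default_rng(layout.seed)
    noise = rng.integers(-NOISE_HALF_RANGE, NOISE_HALF_RANGE + 1, size=(n, n))
    canvas = np.clip(canvas + noise, 0, 255)
    canvas[~inside] = 0.0
    labels[~inside] = -1

    pixels = np.repeat(canvas[..., None], 3, axis=-1).astype(np.uint8)
    still = StillPicture(study_id, camera, segment, index_in_segment, pixels)
    return still, labels


def decode_block(block: np.ndarray) -> ClassLabel | None:
    """Decode the class signature of one aligned 32 x 32 texture block.

    Averages the block over rows, takes the FFT of the 32-sample column
    profile and reads the dominant bin (1..6 cycles <-> classes 0..5); the
    decoded class must also agree with the block's mean intensity.  Returns
    None when no trustworthy signature is present.
    """
    gray = rec601_luma(block).astype(float)
    profile = gray.mean(axis=0)
    spectrum = np.abs(np.fft.rfft(profile - profile.mean()))
    # candidate bins are 1..6 cycles per 32 px; bin b has |FFT| = 16*amplitude
    bins = spectrum[1:7]
    b = int(np.argmax(bins))
    if bins[b] < 16 * AMPLITUDE / 2:  # less than half the expected peak
        return None
    label = ClassLabel(b)
    if abs(gray.mean() - BASE[label.value]) >= 10:
        return None
    return label


def decode_patch(patch: np.ndarray, block_size: int = 32) -> ClassLabel | None:
    """Decode a square patch by majority vote over its aligned blocks.

    Ties break to the lowest class index; returns None when no block carries
    a decodable signature.
    """
    patch = np.asarray(patch)
    side = patch.shape[0]
    votes = np.zeros(len(ClassLabel), dtype=int)
    for r in range(0, side - block_size + 1, block_size):
        for c in range(0, side - block_size + 1, block_size):
            lab = decode_block(patch[r : r + block_size, c : c + block_size])
            if lab is not None:
                votes[lab.value] += 1
    if votes.sum() == 0:
        return None
    return ClassLabel(int(np.argmax(votes)))


def generate_labeled_patchset(
    n_per_class: int,
    seed: int,
    val_fraction: float = 1.0 / 6.0,
    side: int = 128,
) -> tuple[LabeledPatchSet, LabeledPatchSet]:
    """Generate a 6-class texture benchmark, stratified into train/validation.

    Each patch carries its class texture at a random column-phase offset plus
    seeded noise.  ``val_fraction`` of each class (rounded) goes to the
    validation split; the default 1/6 turns ``n_per_class=600`` into the
    3,000 / 600 benchmark split.  Bit-deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label in ClassLabel:
        for _ in range(n_per_class):
            offset = int(rng.integers(0, _PERIOD))
            base_row = texture_value(label, np.arange(offset, offset + side))
            canvas = np.broadcast_to(base_row, (side, side)).copy()
            noise = rng.integers(
                -NOISE_HALF_RANGE, NOISE_HALF_RANGE + 1, size=(side, side)
            )
            canvas = np.clip(canvas + noise, 0, 255)
            X.append(np.repeat(canvas[..., None], 3, axis=-1).astype(np.uint8))
            y.append(label.value)
    X = np.stack(X)
    y = np.asarray(y)

    n_val = round(n_per_class * val_fraction)
    train_idx, val_idx = [], []
    for label in ClassLabel:
        idx = np.flatnonzero(y == label.value)
        idx = rng.permutation(idx)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    train_idx = rng.permutation(np.asarray(train_idx, dtype=int))
    val_idx = rng.permutation(np.asarray(val_idx, dtype=int))
    return (
        LabeledPatchSet(X[train_idx], y[train_idx], "train"),
        LabeledPatchSet(X[val_idx], y[val_idx], "validation"),
    )


# ---------------------------------------------------------------------------
# whole-study generation


ProfileScript = Mapping[Segment, Sequence[tuple[float, float, float, float] | str]]


def default_profile_script(n_per_segment: int = 5) -> dict[Segment, list]:
    """A severity script covering the behaviours a topographic map must show:
    healthy mucosa, mixed severities, an uninterpretable (blank) still, and a
    half-healed rectum.  Fractions sit on the 1/18 grid so the vertical bands
    land on 32-pixel block boundaries of a 576-pixel frame."""
    third, half = 1.0 / 3.0, 0.5
    transverse: list = [(2 * third, third, 0.0, 0.0)] * n_per_segment
    transverse[n_per_segment // 2] = "excluded"
    return {
        Segment.CECUM_ASCENDING: [(1.0, 0.0, 0.0, 0.0)] * n_per_segment,
        Segment.TRANSVERSE: transverse,
        Segment.DESCENDING_SIGMOID: [(third, third, third, 0.0)] * n_per_segment,
        Segment.RECTUM: [(half, 0.0, 0.0, half)] * n_per_segment,
    }


@dataclass
class StudyBundle:
    """A generated dual-camera study plus its scripted ground truth."""

    study_id: str
    stills: list[StillPicture]
    # (camera, segment, index) -> scripted MES0-3 fractions, or None = excluded
    expected: dict[tuple[Camera, Segment, int], tuple[float, ...] | None]
    seed: int


def _layout_for_fractions(
    fractions: Sequence[float], side: int, seed: int
) -> LayoutSpec:
    """Vertical-band layout realizing the target MES0-3 area fractions."""
    total = float(sum(fractions))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    regions = []
    edge = 0
    cum = 0.0
    for k, f in enumerate(fractions):
        if f <= 0:
            continue
        cum += f
        right = side if abs(cum - 1.0) < 1e-9 else int(round(cum * side))
        if right > edge:
            regions.append((Rect(0, edge, side, right), ClassLabel(k)))
            edge = right
    return LayoutSpec(side=side, regions=regions, seed=seed)


def generate_study(
    profile_script: ProfileScript | None = None,
    seed: int = 0,
    study_id: str = "synthetic-study",
    side: int = 576,
) -> StudyBundle:
    """Generate a four-segment, dual-camera still series from a severity script.

    Each script entry is either a 4-tuple of target MES0-3 area fractions
    (summing to 1) or the string ``"excluded"``, which paints the whole frame
    as inadequate-quality texture so the still's severity total area is zero.
    Both cameras receive the same script with independent noise.
    """
    if profile_script is None:
        profile_script = default_profile_script()
    stills: list[StillPicture] = []
    expected: dict[tuple[Camera, Segment, int], tuple[float, ...] | None] = {}
    for cam_i, camera in enumerate(Camera):
        for seg_i, segment in enumerate(Segment):
            entries = profile_script.get(segment, [])
            for idx, entry in enumerate(entries):
                sub_seed = (seed * 8 + cam_i * 4 + seg_i) * 1009 + idx
                if isinstance(entry, str):
                    if entry != "excluded":
                        raise ValueError(f"unknown script entry {entry!r}")
                    layout = LayoutSpec(
                        side=side,
                        regions=[(Rect(0, 0, side, side), ClassLabel.INADEQUATE)],
                        seed=sub_seed,
                    )
                    expected[(camera, segment, idx)] = None
                else:
                    layout = _layout_for_fractions(entry, side, sub_seed)
                    expected[(camera, segment, idx)] = tuple(float(f) for f in entry)
                still, _ = generate_synthetic_still(
                    layout, study_id, camera, segment, idx
                )
                stills.append(still)
    return StudyBundle(study_id, stills, expected, seed)


def write_study(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Write a generated study to disk: PNG stills, a segment manifest CSV and
    a ground-truth JSON, returning the output directory."""
    import imageio.v3 as iio
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for still in bundle.stills:
        name = (
            f"{still.camera.value}_{still.segment.value}_"
            f"{still.index_in_segment:03d}.png"
        )
        iio.imwrite(outdir / name, still.pixels)
    for camera in Camera:
        for segment in Segment:
            rows.append(
                {
                    "source": f"{camera.value}_{segment.value}_*.png",
                    "camera": camera.value,
                    "segment": segment.value,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    truth = {
        f"{cam.value}:{seg.value}:{idx}": frac
        for (cam, seg, idx), frac in bundle.expected.items()
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps({"study_id": bundle.study_id, "seed": bundle.seed,
                    "expected_fractions": truth}, indent=2)
    )
    return outdir
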