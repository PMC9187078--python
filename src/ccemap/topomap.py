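"""Topographic severity maps along the colorectum.

Per-still severity profiles are ordered per camera along the four colorectal
segments (cecum + ascending → transverse → descending + sigmoid → rectum)
and rendered as serial stacked bars: light gray MES0, yellow MES1, magenta
MES2, red MES3, bottom to top.  Stills excluded for zero total area stay in
place as blank columns so the x-axis remains a faithful positional axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import round_half_up
from .ingest import Camera, Segment, SEGMENT_ORDER
from .severity import SeverityProfile

__all__ = [
    "SEVERITY_COLORS",
    "TopographicMap",
    "build_topographic_map",
    "render_map",
    "export_table",
    "read_table",
    "map_to_json",
]

# MES0..MES3 stacked-bar colors, bottom to top
SEVERITY_COLORS = ("lightgray", "gold", "magenta", "red")


@dataclass
class TopographicMap:
    """Ordered per-camera tracks of severity profiles along the colorectum."""

    study_id: str
    tracks: dict[Camera, list[SeverityProfile]] = field(default_factory=dict)

    def track(self, camera: Camera) -> list[SeverityProfile]:
        return self.tracks.get(camera, [])

    def __len__(self) -> int:
        return sum(len(t) for t in self.tracks.values())


def _sort_key(p: SeverityProfile):
    return (SEGMENT_ORDER[p.segment], p.index_in_segment)


def build_topographic_map(
    profiles: Iterable[SeverityProfile], study_id: str = ""
) -> TopographicMap:
    """Assemble profiles into anatomically ordered per-camera tracks.

    Input order is irrelevant; excluded profiles are kept in place.  Two
    profiles sharing (camera, segment, index) are a data error and the
    collision is named.
    """
    by_cam: dict[Camera, list[SeverityProfile]] = {}
    seen: set[tuple[Camera, Segment, int]] = set()
    for p in profiles:
        if p.camera is None or p.segment is None or p.index_in_segment is None:
            raise ValueError(f"profile {p.still_id} lacks camera/segment/index")
        key = (p.camera, p.segment, p.index_in_segment)
        if key in seen:
            raise ValueError(
                f"duplicate profile for camera={p.camera.value} "
                f"segment={p.segment.value} index={p.index_in_segment}"
            )
        seen.add(key)
        by_cam.setdefault(p.camera, []).append(p)
    tracks = {cam: sorted(ps, key=_sort_key) for cam, ps in sorted(
        by_cam.items(), key=lambda kv: kv[0].value)}
    return TopographicMap(study_id=study_id, tracks=tracks)


def render_map(
    tmap: TopographicMap,
    out_path: str | Path | None = None,
    format: str | None = None,
):
    """Render the map as one stacked-bar panel per camera track.

    Every profile becomes one column (excluded stills as blank columns of
    zero height); internal segment boundaries are marked and labelled.
    Returns the matplotlib figure; saves to `out_path` when given (`format`
    ``svg``/``png`` overrides the path suffix).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not tmap.tracks:
        raise ValueError("cannot render an empty topographic map")
    n_panels = len(tmap.tracks)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(max(6, len(tmap) // n_panels * 0.12), 3 * n_panels),
        squeeze=False,
    )
    for ax, (camera, profiles) in zip(axes.ravel(), tmap.tracks.items()):
        x = np.arange(len(profiles))
        heights = np.array(
            [p.fractions if not p.excluded else (0.0, 0.0, 0.0, 0.0)
             for p in profiles]
        ) * 100.0
        bottom = np.zeros(len(profiles))
        for k, color in enumerate(SEVERITY_COLORS):
            ax.bar(x, heights[:, k], bottom=bottom, width=1.0, color=color,
                   edgecolor="none", label=f"MES{k}%area")
            bottom += heights[:, k]
        # internal segment boundaries
        boundaries = []
        for i in range(1, len(profiles)):
            if profiles[i].segment != profiles[i - 1].segment:
                boundaries.append(i - 0.5)
        for b in boundaries:
            ax.axvline(b, color="black", linewidth=0.8)
        # one tick at the centre of each segment run
        ticks, ticklabels, run_start = [], [], 0
        for i in range(1, len(profiles) + 1):
            if i == len(profiles) or profiles[i].segment != profiles[run_start].segment:
                ticks.append((run_start + i - 1) / 2)
                ticklabels.append(profiles[run_start].segment.value)
                run_start = i
        ax.set_xticks(ticks)
        ax.set_xticklabels(ticklabels, fontsize=7)
        ax.set_ylim(0, 100)
        ax.set_ylabel("% area")
        suffix = "-f" if camera == Camera.FORWARD else "-b"
        ax.set_title(f"{tmap.study_id}{suffix}")
    axes.ravel()[0].legend(loc="upper right", fontsize=6, ncol=4)
    fig.tight_layout()
    if out_path is not None:
        out_path = Path(out_path)
        if format:
            out_path = out_path.with_suffix(f".{format}")
        try:
            fig.savefig(out_path)
        except OSError as exc:
            raise OSError(f"cannot write figure to {out_path}: {exc}") from exc
    return fig


def export_table(tmap: TopographicMap, out_path: str | Path | None = None) -> pd.DataFrame:
    """Per-still severity table: raw areas, raw fractions and half-up
    1-decimal percentages, one row per still in track order.

    Excluded stills keep their row (flagged, with empty percentage cells).
    Percent rows may sum to 99.9 or 100.1 from rounding residue; the raw
    fractions are emitted alongside for exact reuse.
    """
    rows = []
    for camera, profiles in tmap.tracks.items():
        for p in profiles:
            row = {
                "study_id": tmap.study_id,
                "camera": camera.value,
                "segment": p.segment.value,
                "index": p.index_in_segment,
                "still_id": p.still_id,
                "excluded": p.excluded,
            }
            for k in range(4):
                row[f"area{k}"] = p.areas[k]
            row["total"] = p.total_area
            for k in range(4):
                row[f"frac{k}"] = None if p.excluded else p.fractions[k]
                row[f"pct{k}"] = (
                    None if p.excluded else round_half_up(p.fractions[k] * 100.0, 1)
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_path is not None:
        try:
            df.to_csv(out_path, index=False, float_format="%.10g")
        except OSError as exc:
            raise OSError(f"cannot write table to {out_path}: {exc}") from exc
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-import an exported severity table (excluded rows keep NaN cells)."""
    return pd.read_csv(path)


def map_to_json(tmap: TopographicMap, out_path: str | Path | None = None) -> str:
    """JSON dump of the full map for programmatic reuse."""
    payload = {
        "study_id": tmap.study_id,
        "tracks": {
            cam.value: [
                {
                    "still_id": p.still_id,
                    "segment": p.segment.value,
                    "index": p.index_in_segment,
                    "excluded": p.excluded,
                    "areas": list(p.areas),
                    "total_area": p.total_area,
                    "fractions": None if p.excluded else list(p.fractions),
                }
                for p in profiles
            ]
            for cam, profiles in tmap.tracks.items()
        },
    }
    text = json.dumps(payload, indent=2)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
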