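"""End-to-end orchestration: stills -> patches -> labels -> profiles -> map.

Everything here is a pure function of (inputs, config, seeds); a run writes
its resolved configuration next to its outputs so any run can be reproduced
from the dump plus the inputs.
"""

from __future__ import annotations

import dataclasses
import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import make_oracle_classifier, load_model, predict_patches
from .ingest import (
    EffectiveRegionMask,
    Segment,
    SegmentManifest,
    StillPicture,
    estimate_fov_mask,
    load_mask_file,
    load_still,
    read_manifest,
)
from .patching import ExclusionRule, extract_patches, patch_inventory
from .severity import ClassifiedGrid, severity_profile
from .topomap import TopographicMap, build_topographic_map, export_table, map_to_json, render_map

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "classify_still",
    "process_stills",
    "load_study_from_dir",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    input_dir: str = "."
    output_dir: str = "out"
    study_id: str = "study"
    manifest: str = "manifest.csv"
    classifier: str = "oracle"  # "oracle" | path to a saved model
    mask_mode: str = "estimate"  # "estimate" | "file" | "none"
    mask_file: str | None = None
    seed: int = 0
    exclusion: dict = field(default_factory=dict)  # ExclusionRule overrides
    figure_format: str = "png"

    def rule(self) -> ExclusionRule:
        return ExclusionRule(**self.exclusion)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _resolve_mask(
    still: StillPicture, mask_mode: str, mask_file: str | None
) -> EffectiveRegionMask | None:
    if mask_mode == "none":
        return None
    if mask_mode == "file":
        if not mask_file:
            raise ValueError("mask_mode 'file' requires mask_file")
        return load_mask_file(mask_file)
    if mask_mode == "estimate":
        return estimate_fov_mask(still)
    raise ValueError(f"unknown mask_mode {mask_mode!r}")


def classify_still(
    still: StillPicture,
    model,
    rule: ExclusionRule = ExclusionRule(),
    mask_mode: str = "estimate",
    mask_file: str | None = None,
) -> ClassifiedGrid:
    """Tile, exclude and classify one still into a ClassifiedGrid."""
    mask = _resolve_mask(still, mask_mode, mask_file)
    specs = extract_patches(still, mask, rule)
    if specs:
        patches = np.stack([still.pixels[s.slices()] for s in specs])
        labels = [lab for lab, _ in predict_patches(model, patches)]
    else:
        labels = []
    h, w = still.shape
    return ClassifiedGrid(
        still_id=still.still_id,
        items=list(zip(specs, labels)),
        image_height=h,
        image_width=w,
        camera=still.camera,
        segment=still.segment,
        index_in_segment=still.index_in_segment,
    )


def process_stills(
    stills: list[StillPicture],
    model,
    rule: ExclusionRule = ExclusionRule(),
    mask_mode: str = "estimate",
    study_id: str = "",
) -> TopographicMap:
    """Classify every still and assemble the topographic severity map."""
    profiles = [
        severity_profile(classify_still(s, model, rule, mask_mode)) for s in stills
    ]
    n_excl = sum(p.excluded for p in profiles)
    logger.info(
        "processed %d stills (%d excluded for zero total area)",
        len(profiles), n_excl,
    )
    return build_topographic_map(profiles, study_id=study_id)


def load_study_from_dir(
    input_dir: str | Path, manifest: SegmentManifest, study_id: str
) -> list[StillPicture]:
    """Load stills matching each manifest entry's file glob, in name order."""
    input_dir = Path(input_dir)
    stills = []
    for entry in manifest.entries:
        matches = sorted(
            p for p in input_dir.iterdir()
            if fnmatch.fnmatch(p.name, entry.source)
        )
        for idx, path in enumerate(matches):
            stills.append(load_still(path, study_id, entry.camera, entry.segment, idx))
    if not stills:
        raise ValueError(f"manifest matched no stills under {input_dir}")
    return stills


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full chain and write all stage outputs to the output directory.

    Outputs: patch inventory CSV, severity table CSV, map JSON, map figure,
    and the resolved config (``config_resolved.yaml``).
    """
    manifest = read_manifest(Path(config.input_dir) / config.manifest)
    if not manifest.entries:
        raise ValueError("manifest is empty; nothing to process")
    stills = load_study_from_dir(config.input_dir, manifest, config.study_id)
    rule = config.rule()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.classifier == "oracle":
        model = make_oracle_classifier()
    else:
        model_path = Path(config.classifier)
        if not model_path.exists():
            raise FileNotFoundError(
                f"classifier model not found at {model_path}; train one with "
                "the 'train' subcommand or use classifier 'oracle'"
            )
        model = load_model(model_path)

    inventories = []
    for still in stills:
        mask = _resolve_mask(still, config.mask_mode, config.mask_file)
        inventories.append(patch_inventory(still, mask, rule))
    inventory = pd.concat(inventories, ignore_index=True)
    inventory.to_csv(outdir / "patch_inventory.csv", index=False)
    n_total = len(inventory)
    n_inadequate_quality = int(inventory["excluded"].sum())
    logger.info(
        "patch inventory: %d grid windows, %d excluded (%.1f%%)",
        n_total, n_inadequate_quality,
        100.0 * n_inadequate_quality / max(n_total, 1),
    )

    tmap = process_stills(
        stills, model, rule, config.mask_mode, study_id=config.study_id
    )
    export_table(tmap, outdir / "severity_table.csv")
    map_to_json(tmap, outdir / "topographic_map.json")
    fig = render_map(
        tmap, outdir / f"topographic_map.{config.figure_format}"
    )
    import matplotlib.pyplot as plt

    plt.close(fig)
    config.to_yaml(outdir / "config_resolved.yaml")
    return outdir
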