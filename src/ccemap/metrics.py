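"""Classification bookkeeping: confusion matrices, accuracies, composition.

The package ships the published validation confusion matrix of the clinical
patch classifier and the per-class dataset composition as verbatim CSV
fixtures; this module recomputes the derived quantities — per-class and
overall accuracy (half-up, 3 decimals) and per-class shares of the pooled
patch total (half-up, 1-decimal percent) — from the raw counts, which is the
package's exact, data-free evaluation surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from ._util import round_ratio_half_up
from .classify import CLASS_NAMES, N_CLASSES

__all__ = [
    "ConfusionMatrix",
    "DatasetComposition",
    "confusion_matrix",
    "per_class_accuracy",
    "overall_accuracy",
    "composition_report",
    "load_reference_confusion",
    "load_reference_composition",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be 6x6, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_labels(
        cls, true_labels: Sequence[int], predicted: Sequence[int]
    ) -> "ConfusionMatrix":
        return confusion_matrix(true_labels, predicted)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.counts, index=list(CLASS_NAMES), columns=list(CLASS_NAMES)
        ).to_csv(path, index_label="true_class")


@dataclass(frozen=True)
class DatasetComposition:
    """Per-class patch counts for one named split."""

    name: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CLASSES:
            raise ValueError("composition needs one count per class")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def confusion_matrix(
    true_labels: Sequence[int], predicted: Sequence[int]
) -> ConfusionMatrix:
    """counts[i][j] = items with true class i predicted as class j."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: {t.size} true labels vs {p.size} predictions"
        )
    if t.size == 0:
        return ConfusionMatrix(np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64))
    if t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES:
        raise ValueError("labels must lie in 0..5")
    return ConfusionMatrix(
        _sk_confusion_matrix(t, p, labels=np.arange(N_CLASSES))
    )


def per_class_accuracy(cm: ConfusionMatrix, decimals: int = 3) -> np.ndarray:
    """Per-class accuracy diag/rowsum, half-up to `decimals`; empty rows NaN."""
    out = np.full(N_CLASSES, np.nan)
    for i in range(N_CLASSES):
        row = int(cm.row_sums[i])
        if row > 0:
            out[i] = round_ratio_half_up(int(cm.counts[i, i]), row, decimals)
    return out


def overall_accuracy(cm: ConfusionMatrix, decimals: int = 3) -> float:
    """Overall accuracy trace/total, half-up to `decimals`."""
    if cm.total == 0:
        raise ValueError("overall accuracy undefined for an empty matrix")
    return round_ratio_half_up(int(np.trace(cm.counts)), cm.total, decimals)


def composition_report(splits: Sequence[DatasetComposition]) -> pd.DataFrame:
    """Composition table: per-class counts per split, totals, and each class's
    share of the pooled grand total as a half-up 1-decimal percent."""
    if not splits:
        raise ValueError("need at least one split")
    data = {"class": list(CLASS_NAMES)}
    for s in splits:
        data[s.name] = list(s.counts)
    df = pd.DataFrame(data)
    df["all_splits"] = df[[s.name for s in splits]].sum(axis=1)
    grand_total = int(df["all_splits"].sum())
    df["share_pct"] = [
        round_ratio_half_up(int(n) * 100, grand_total, 1) if grand_total else np.nan
        for n in df["all_splits"]
    ]
    totals = {"class": "Total", "all_splits": grand_total, "share_pct": 100.0}
    for s in splits:
        totals[s.name] = s.total
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def _data_path(name: str):
    return resources.files("ccemap.data").joinpath(name)


def load_reference_confusion() -> ConfusionMatrix:
    """The packaged validation confusion matrix of the clinical classifier."""
    with resources.as_file(_data_path("validation_confusion.csv")) as p:
        return ConfusionMatrix.from_csv(p)


def load_reference_composition() -> tuple[DatasetComposition, DatasetComposition]:
    """The packaged (training, validation) per-class dataset composition."""
    with resources.as_file(_data_path("dataset_composition.csv")) as p:
        df = pd.read_csv(p)
    return (
        DatasetComposition("training", tuple(int(x) for x in df["training"])),
        DatasetComposition("validation", tuple(int(x) for x in df["validation"])),
    )
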