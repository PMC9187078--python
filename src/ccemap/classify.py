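"""Six-class patch classification behind a uniform fit/predict interface.

Patches trimmed from a capsule still are graded into six categories: Mayo
endoscopic subscore (MES) 0-3, inadequate quality for evaluation, and ileal
mucosa.  White scars and inflammatory polyps count as MES0 (inactive
findings).  Two interchangeable classifiers honour the same contract:

* :class:`MLPPatchClassifier` — a trainable multilayer-perceptron classifier
  (Adam optimizer, cross-entropy loss, seeded) operating on bilinearly
  resized, mean-pooled, [0, 1]-scaled patch pixels; and
* :class:`OracleClassifier` — a deterministic decoder of the synthetic
  texture signatures, used to verify the downstream severity and mapping
  stages independently of any training run.

Both are scikit-learn estimators (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
The predict contract: the label is the argmax of a 6-way score vector that
sums to 1, with ties broken toward the lowest class index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassLabel",
    "CLASS_NAMES",
    "TrainConfig",
    "resize_patch",
    "MLPPatchClassifier",
    "OracleClassifier",
    "make_oracle_classifier",
    "train_classifier",
    "predict_patches",
    "save_model",
    "load_model",
]


class ClassLabel(IntEnum):
    """The six patch categories."""

    MES0 = 0
    MES1 = 1
    MES2 = 2
    MES3 = 3
    INADEQUATE = 4  # inadequate quality for evaluation (residue, bubbles, blur)
    ILEAL = 5  # ileal mucosa, seen before the capsule enters the colon


CLASS_NAMES = tuple(c.name for c in ClassLabel)
N_CLASSES = len(ClassLabel)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters of the patch classifier.

    Defaults: Adam optimizer, cross-entropy loss, 50 epochs, batch size 256,
    learning rate 2.5e-4, six output classes, 224-pixel input side.  The seed
    is mandatory so runs are reproducible by construction.
    """

    seed: int
    optimizer: str = "adam"
    learning_rate: float = 2.5e-4
    epochs: int = 50
    batch_size: int = 256
    loss: str = "cross_entropy"
    n_classes: int = N_CLASSES
    input_side: int = 224
    hidden_layers: tuple[int, ...] = (128,)
    feature_side: int = 32
    class_weight: str | None = None  # None or "balanced" (inverse-frequency)


def resize_patch(patch: np.ndarray, target_side: int = 224) -> np.ndarray:
    """Bilinearly resize a square patch; values stay clipped to [0, 255].

    Resizing to the input side is a no-op returning a copy.
    """
    patch = np.asarray(patch)
    if patch.ndim not in (2, 3) or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square, got shape {patch.shape}")
    if patch.shape[0] == target_side:
        return patch.copy()
    img = Image.fromarray(patch.astype(np.uint8))
    out = img.resize((target_side, target_side), Image.BILINEAR)
    return np.clip(np.asarray(out), 0, 255).astype(np.uint8)


def _as_patch_array(patches: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    X = np.asarray(patches)
    if X.ndim == 3:  # single patch
        X = X[None]
    if X.ndim != 4 or X.shape[1] != X.shape[2] or X.shape[3] != 3:
        raise ValueError(
            f"expected n x side x side x 3 patch array, got shape {X.shape}"
        )
    return X


class MLPPatchClassifier(BaseEstimator, ClassifierMixin):
    """Trainable patch classifier: resized pixels -> mean pooling -> MLP.

    Each patch is bilinearly resized to ``input_side``, mean-pooled down to
    ``feature_side`` (so ``input_side`` must be divisible by ``feature_side``),
    scaled to [0, 1], flattened, and standardized per feature on the training
    set; a multilayer perceptron trained with Adam on cross-entropy loss
    produces the 6-way scores.  With a fixed ``seed`` and fixed data ordering,
    two runs produce identical per-epoch loss curves.
    """

    def __init__(
        self,
        seed: int = 0,
        learning_rate: float = 2.5e-4,
        epochs: int = 50,
        batch_size: int = 256,
        input_side: int = 224,
        hidden_layers: tuple[int, ...] = (128,),
        feature_side: int = 32,
        class_weight: str | None = None,
    ) -> None:
        self.seed = seed
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_side = input_side
        self.hidden_layers = hidden_layers
        self.feature_side = feature_side
        self.class_weight = class_weight

    @classmethod
    def from_config(cls, config: TrainConfig) -> "MLPPatchClassifier":
        return cls(
            seed=config.seed,
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            input_side=config.input_side,
            hidden_layers=config.hidden_layers,
            feature_side=config.feature_side,
            class_weight=config.class_weight,
        )

    # -- feature pipeline ---------------------------------------------------

    def _features(self, patches: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
        X = _as_patch_array(patches)
        if self.input_side % self.feature_side:
            raise ValueError("input_side must be divisible by feature_side")
        pool = self.input_side // self.feature_side
        feats = np.empty(
            (len(X), self.feature_side, self.feature_side, 3), dtype=np.float64
        )
        for i, patch in enumerate(X):
            resized = resize_patch(patch, self.input_side).astype(np.float64)
            pooled = resized.reshape(
                self.feature_side, pool, self.feature_side, pool, 3
            ).mean(axis=(1, 3))
            feats[i] = pooled
        return (feats / 255.0).reshape(len(X), -1)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        """Fit on patches X (n x side x side x 3) and labels y in 0..5."""
        y = np.asarray(y, dtype=int)
        if len(y) == 0:
            raise ValueError("empty training set")
        if np.unique(y).size < 2:
            raise ValueError(
                "training requires examples of at least 2 classes "
                "(cross-entropy is degenerate on a single class)"
            )
        feats = self._features(X)
        if self.class_weight == "balanced":
            # inverse-frequency balancing by repetition (keeps the solver simple)
            counts = np.bincount(y, minlength=N_CLASSES)
            top = counts.max()
            idx = np.concatenate(
                [np.repeat(np.flatnonzero(y == c), max(1, round(top / n)))
                 for c, n in enumerate(counts) if n > 0]
            )
            idx.sort()
            feats, y = feats[idx], y[idx]
        self._mlp = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layers),
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, len(y)),
            max_iter=self.epochs,
            n_iter_no_change=self.epochs,  # run all epochs; no early stop
            shuffle=True,
            random_state=self.seed,
        )
        self._scaler = StandardScaler().fit(feats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at small epoch counts
            self._mlp.fit(self._scaler.transform(feats), y)
        self.classes_ = np.arange(N_CLASSES)
        self.loss_curve_ = list(self._mlp.loss_curve_)
        self.n_features_in_ = feats.shape[1]
        self.training_log_ = pd.DataFrame(
            {"epoch": np.arange(1, len(self.loss_curve_) + 1),
             "loss": self.loss_curve_}
        )
        self.normalization_ = (
            "pixels scaled to [0, 1]; per-feature standardization "
            "(zero mean, unit variance) fit on the training set"
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_mlp")
        feats = self._scaler.transform(self._features(X))
        proba = self._mlp.predict_proba(feats)
        out = np.zeros((len(feats), N_CLASSES))
        out[:, self._mlp.classes_] = proba
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class OracleClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic decoder of the synthetic class-texture signatures.

    Decodes each aligned 32x32 block of a patch via its FFT signature and
    votes; a patch with no decodable signature is graded INADEQUATE with a
    warning.  ``fit`` is a no-op kept for estimator-API compatibility.
    """

    def __init__(self, texture_key: dict | None = None, block_size: int = 32) -> None:
        self.texture_key = texture_key
        self.block_size = block_size

    def fit(self, X=None, y=None):
        from . import synthfix

        key = self.texture_key
        if key is None:
            key = {cycles: ClassLabel(i) for i, cycles in enumerate(synthfix.CYCLES)}
        covered = set(key.values())
        if covered != set(ClassLabel):
            raise ValueError(
                f"texture key must cover all 6 classes, missing "
                f"{sorted(set(ClassLabel) - covered)}"
            )
        self.key_ = dict(key)
        self.classes_ = np.arange(N_CLASSES)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "key_")
        from . import synthfix

        X = _as_patch_array(X)
        out = np.zeros((len(X), N_CLASSES))
        n_unknown = 0
        for i, patch in enumerate(X):
            label = synthfix.decode_patch(patch, self.block_size)
            if label is None:
                n_unknown += 1
                label = ClassLabel.INADEQUATE
            out[i, label.value] = 1.0
        if n_unknown:
            warnings.warn(
                f"{n_unknown} patch(es) carried no decodable texture signature; "
                "graded INADEQUATE",
                stacklevel=2,
            )
        return out

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def make_oracle_classifier(texture_key: dict | None = None) -> OracleClassifier:
    """A fitted oracle classifier decoding the synthetic texture signatures."""
    return OracleClassifier(texture_key=texture_key).fit()


def train_classifier(train_set, config: TrainConfig):
    """Train the patch classifier on a labeled patch set.

    Returns ``(model, log)`` where `log` is a per-epoch loss table.
    """
    model = MLPPatchClassifier.from_config(config).fit(train_set.X, train_set.y)
    model.config_ = config
    return model, model.training_log_


def predict_patches(model, patches) -> list[tuple[ClassLabel, np.ndarray]]:
    """Classify patches, preserving order.

    Returns one ``(label, scores)`` pair per patch; scores are the 6-way
    probability vector (sums to 1), label its argmax with low-index ties.
    """
    proba = model.predict_proba(patches)
    return [(ClassLabel(int(np.argmax(p))), p) for p in proba]


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted model plus a JSON sidecar with its configuration."""
    path = Path(path)
    joblib.dump(model, path)
    meta: dict = {"estimator": type(model).__name__}
    cfg = getattr(model, "config_", None)
    if cfg is not None:
        meta["train_config"] = asdict(cfg)
    meta["normalization"] = getattr(model, "normalization_", None)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path):
    return joblib.load(path)
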