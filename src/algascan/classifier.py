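"""Per-pixel spectral classification with a one-dimensional CNN.

Each pixel of a reconstructed 45-band reflectance cube is an independent 1-D
sample: wavelength is encoded in the array position, so one-dimensional
convolutions extract local spectral shape features (slopes, absorption dips)
irrespective of where in the spectrum they occur.  The network is

    conv(32, k=3, s=1, p=1) -> ReLU -> maxpool(2, 2) -> dropout(0.25)
 -> conv(64, k=3, s=1, p=1) -> ReLU -> maxpool(2, 2) -> dropout(0.25)
 -> flatten -> dense(128) -> ReLU -> dense(128) -> ReLU -> linear(n_classes)

trained with softmax cross-entropy and Adam on labeled spectra split 90/10
into training and validation sets (stratified by class).  For 45 input bands
the flatten length is 64 * floor(floor(45/2)/2) = 704.  Training is fully
deterministic for a fixed seed.

Evaluation follows the standard segmentation protocol: per-class precision,
recall, and F1 over annotated pixels, macro-averaged over the macroalgae
classes with the background excluded from the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .hypercube import Hypercube
from .library import Annotation, SpectralLibrary

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ClassMetrics",
    "SpectralCNN",
    "TrainResult",
    "PredictionResult",
    "build_model",
    "split_train_val",
    "train_model",
    "predict_cube",
    "evaluate_segmentation",
    "save_model",
    "load_model",
]

UNKNOWN_LABEL = -1  # label assigned to pixels with invalid bands


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the 1-D CNN."""

    n_bands: int = 45
    n_classes: int = 5
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    dropout: float = 0.25
    dense_units: int = 128

    def __post_init__(self) -> None:
        for name in ("n_classes", "conv1_filters", "conv2_filters",
                     "kernel_size", "pool_size", "dense_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def flatten_length(self) -> int:
        pooled = (self.n_bands // self.pool_size) // self.pool_size
        return self.conv2_filters * pooled


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule: Adam, cross-entropy, stratified 90/10 split."""

    epochs: int = 300
    batch_size: int = 256
    learning_rate: float = 1e-3
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie strictly between 0 and 1")


class SpectralCNN:
    """The 1-D CNN with its class-name vocabulary."""

    def __init__(self, spec: ModelSpec, class_names: list[str] | None = None,
                 seed: int = 0):
        if spec.n_bands < 2 * spec.pool_size:
            raise ValueError(
                "n_bands too small: two pooling stages would collapse the input"
            )
        if class_names is not None and len(class_names) != spec.n_classes:
            raise ValueError("class_names length must equal n_classes")
        self.spec = spec
        self.class_names = class_names or [str(i) for i in range(spec.n_classes)]
        self.rng = np.random.default_rng(seed)
        k, p = spec.kernel_size, spec.kernel_size // 2
        self.net = nn.Sequential([
            nn.Conv1d(1, spec.conv1_filters, k, padding=p, rng=self.rng),
            nn.ReLU(),
            nn.MaxPool1d(spec.pool_size),
            nn.Dropout(spec.dropout, rng=self.rng),
            nn.Conv1d(spec.conv1_filters, spec.conv2_filters, k, padding=p,
                      rng=self.rng),
            nn.ReLU(),
            nn.MaxPool1d(spec.pool_size),
            nn.Dropout(spec.dropout, rng=self.rng),
            nn.Flatten(),
            nn.Dense(spec.flatten_length, spec.dense_units, rng=self.rng),
            nn.ReLU(),
            nn.Dense(spec.dense_units, spec.dense_units, rng=self.rng),
            nn.ReLU(),
            nn.Dense(spec.dense_units, spec.n_classes, rng=self.rng,
                     relu_init=False),
        ])

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward pass; ``x`` is (n, n_bands) spectra."""
        if x.ndim != 2 or x.shape[1] != self.spec.n_bands:
            raise ValueError(
                f"expected (n, {self.spec.n_bands}) spectra, got {x.shape}"
            )
        return self.net.forward(
            x.astype(np.float32)[:, None, :], train=train
        )

    def predict_proba(self, x: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        out = np.empty((len(x), self.spec.n_classes), dtype=np.float32)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = nn.softmax(self.logits(x[i : i + batch_size]))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}_{name}": layer.params[name]
            for i, layer in enumerate(self.net.layers)
            for name in layer.params
        }

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.net.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(arrays[f"layer{i}_{name}"],
                                                dtype=np.float32)


def build_model(spec: ModelSpec | None = None,
                class_names: list[str] | None = None,
                seed: int = 0) -> SpectralCNN:
    """Instantiate the 1-D CNN for a given architecture spec."""
    return SpectralCNN(spec or ModelSpec(), class_names=class_names, seed=seed)


def split_train_val(
    library: SpectralLibrary, fraction: float = 0.9, seed: int = 0
) -> tuple[SpectralLibrary, SpectralLibrary]:
    """Disjoint, exhaustive, class-stratified split of a spectral library."""
    if len(library) < 10:
        raise ValueError("need at least 10 records to split")
    idx = np.arange(len(library))
    train_idx, val_idx = train_test_split(
        idx, train_size=fraction, stratify=library.labels, random_state=seed
    )
    return library.subset(np.sort(train_idx)), library.subset(np.sort(val_idx))


@dataclass
class TrainResult:
    model: SpectralCNN
    train_losses: list[float]
    val_losses: list[float]


def train_model(
    model: SpectralCNN,
    library: SpectralLibrary,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train on a labeled library; returns per-epoch train/validation losses.

    The library's classes must be a subset of the model's vocabulary; every
    model class present in the library must have at least one record.
    """
    config = config or TrainConfig()
    name_to_idx = {n: i for i, n in enumerate(model.class_names)}
    unknown = set(np.unique(library.labels)) - set(name_to_idx)
    if unknown:
        raise ValueError(f"library classes {sorted(unknown)} not in the model")
    counts = library.class_counts()
    empty = [c for c in counts.index if counts[c] == 0]
    if empty:
        raise ValueError(f"empty class(es) {empty}")

    train_lib, val_lib = split_train_val(
        library, fraction=config.train_fraction, seed=config.seed
    )
    x_tr = train_lib.spectra
    y_tr = np.array([name_to_idx[l] for l in train_lib.labels])
    x_va = val_lib.spectra
    y_va = np.array([name_to_idx[l] for l in val_lib.labels])

    opt = nn.Adam(model.net, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    train_losses, val_losses = [], []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = order[i : i + config.batch_size]
            logits = model.logits(x_tr[batch], train=True)
            loss, grad = nn.cross_entropy(logits, y_tr[batch])
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        train_losses.append(epoch_loss / max(n_batches, 1))
        val_logits = model.logits(x_va)
        val_loss, _ = nn.cross_entropy(val_logits, y_va)
        val_losses.append(val_loss)
    return TrainResult(model=model, train_losses=train_losses, val_losses=val_losses)


@dataclass
class PredictionResult:
    """Pixelwise segmentation of a cube."""

    label_map: np.ndarray  # (rows, cols) int; UNKNOWN_LABEL where invalid
    class_names: list[str]
    coverage: dict[str, float]  # share of *valid* pixels per class (sums to 1)

    def label_name_map(self) -> np.ndarray:
        names = np.array(self.class_names + ["unknown"], dtype=object)
        return names[self.label_map]


def predict_cube(model: SpectralCNN, cube: Hypercube) -> PredictionResult:
    """Argmax class per valid pixel; invalid pixels are labeled unknown."""
    if cube.n_bands != model.spec.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but the model expects "
            f"{model.spec.n_bands}"
        )
    valid = cube.pixel_valid()
    labels = np.full(valid.shape, UNKNOWN_LABEL, dtype=int)
    if valid.any():
        pred = model.predict(cube.values[valid])
        labels[valid] = pred
    n_valid = int(valid.sum())
    coverage = {
        name: float((labels == i).sum() / n_valid) if n_valid else 0.0
        for i, name in enumerate(model.class_names)
    }
    return PredictionResult(
        label_map=labels, class_names=list(model.class_names), coverage=coverage
    )


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus macro averages over the
    macroalgae classes (background excluded)."""

    per_class: pd.DataFrame  # index class, columns precision/recall/f1/support
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        df.loc["macro_average"] = [
            self.macro_precision, self.macro_recall, self.macro_f1,
            df["support"].sum(),
        ]
        return df


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def evaluate_segmentation(
    prediction: PredictionResult,
    annotations: list[Annotation],
    cube_id: str,
    background_class: str = "grey",
) -> ClassMetrics:
    """Precision/recall/F1 of a predicted label map against annotated boxes.

    Only annotated pixels enter the confusion counts.  Classes absent from
    the ground truth report NaN metrics; the macro average runs over the
    non-background classes with defined metrics.
    """
    name_to_idx = {n: i for i, n in enumerate(prediction.class_names)}
    rows, cols = prediction.label_map.shape
    truth = np.full((rows, cols), UNKNOWN_LABEL, dtype=int)
    for ann in annotations:
        if ann.cube_id != cube_id:
            continue
        if ann.class_label not in name_to_idx:
            raise ValueError(f"annotation class {ann.class_label!r} unknown to model")
        cmin, rmin, cmax, rmax = ann.box
        if not (0 <= cmin < cmax <= cols and 0 <= rmin < rmax <= rows):
            raise ValueError(f"annotation box {ann.box} exceeds the label map")
        region = truth[rmin:rmax, cmin:cmax]
        region[region == UNKNOWN_LABEL] = name_to_idx[ann.class_label]
    annotated = truth != UNKNOWN_LABEL
    if not annotated.any():
        raise ValueError(f"no annotations found for cube {cube_id!r}")
    t = truth[annotated]
    p = prediction.label_map[annotated]

    records = {}
    for name, idx in name_to_idx.items():
        tp = int(np.sum((t == idx) & (p == idx)))
        fp = int(np.sum((t != idx) & (p == idx)))
        fn = int(np.sum((t == idx) & (p != idx)))
        support = int(np.sum(t == idx))
        if support == 0 and fp == 0:
            records[name] = (np.nan, np.nan, np.nan, 0)
        else:
            precision, recall, f1 = _prf(tp, fp, fn)
            records[name] = (precision, recall, f1, support)
    per_class = pd.DataFrame.from_dict(
        records, orient="index",
        columns=["precision", "recall", "f1", "support"],
    )
    algae = per_class.drop(index=background_class, errors="ignore")
    return ClassMetrics(
        per_class=per_class,
        macro_precision=float(np.nanmean(algae["precision"])),
        macro_recall=float(np.nanmean(algae["recall"])),
        macro_f1=float(np.nanmean(algae["f1"])),
    )


def save_model(model: SpectralCNN, path_prefix) -> None:
    """Persist weights (compressed arrays) plus a JSON architecture sidecar."""
    path_prefix = str(path_prefix)
    np.savez_compressed(path_prefix + ".npz", **model.state_arrays())
    sidecar = {"spec": asdict(model.spec), "class_names": model.class_names}
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path_prefix) -> SpectralCNN:
    path_prefix = str(path_prefix)
    with open(path_prefix + ".json") as fh:
        sidecar = json.load(fh)
    model = SpectralCNN(
        ModelSpec(**sidecar["spec"]), class_names=sidecar["class_names"]
    )
    with np.load(path_prefix + ".npz") as z:
        model.load_state_arrays(dict(z))
    return model
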