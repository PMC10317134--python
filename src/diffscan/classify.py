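"""The three frame classifiers and the dataset-split protocol.

Two classifiers consume the 516-value radial intensity average (RIA)
profile: a fully connected network with a single 30-unit hidden layer
trained on categorical cross-entropy, and an RBF-kernel support vector
machine.  The third is a convolutional network that sees only the central
crop of the recentred frame — a 150-pixel radius, which at the default
geometry reaches 2.7 Å and contains the primary amorphous-carbon and
water rings but excludes everything beyond.

Training pools are split 90/10 into training and validation at the frame
level, stratified by class; held-out test scans never touch training or
tuning.  Feature standardization statistics are computed on training data
only and stored with each model, so a saved model reproduces its
predictions exactly after reloading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import loguniform
from sklearn.model_selection import RandomizedSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._cnn import SmallCNN
from .labeling import ClassLabel
from .preprocess import CenteredFrame

__all__ = [
    "SplitSpec",
    "FCNNConfig",
    "SVMConfig",
    "CNNConfig",
    "FeatureScaler",
    "RIAClassifier",
    "CNNClassifier",
    "split_datasets",
    "crop_central",
    "train_fcnn",
    "train_svm",
    "train_cnn",
    "tune_svm",
    "predict_map",
    "load_classifier",
]


# --------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class SplitSpec:
    """Frame-level split protocol: ``train_fraction`` of the pooled training
    scans for fitting, the rest for validation; ``test_ids`` name scans that
    are held out entirely."""

    train_fraction: float = 0.9
    test_ids: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FCNNConfig:
    input_dim: int = 516
    hidden_units: int = 30
    max_epochs: int = 400
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    # gamma "auto" = 1/n_features: the scale-free RBF width on features that
    # the bundled scaler has already standardized; with moderate C this
    # generalizes across sessions instead of memorizing intensity levels
    C: float = 1.0
    gamma: float | str = "auto"
    search_budget: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class CNNConfig:
    crop_radius: int = 150
    downsample: int = 6
    channels: tuple = (8, 8, 16, 16, 32, 32)
    dropout: float = 0.25
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 8
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != 6:
            raise ValueError("exactly six convolution layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def input_hw(self) -> tuple[int, int]:
        side = (2 * self.crop_radius + 1) // self.downsample
        return (side, side)


# --------------------------------------------------------------------------
# feature plumbing


class FeatureScaler:
    """Per-feature standardization fitted on training data; NaN feature
    values (empty RIA annuli) are imputed as 0 *after* standardization, so
    the feature length stays fixed."""

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=np.float64)
        import warnings

        with warnings.catch_warnings():  # all-NaN features are expected (outer annuli)
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_ = np.nan_to_num(np.nanmean(X, axis=0))
            self.std_ = np.nan_to_num(np.nanstd(X, axis=0))
        self.std_[~(self.std_ > 0)] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_
        return np.nan_to_num(X)


def _check_classes(y: np.ndarray) -> None:
    present = set(int(v) for v in np.unique(y))
    if len(present) < 2:
        missing = [c.name for c in ClassLabel if int(c) not in present]
        raise ValueError(f"training data contains a single class; missing: {', '.join(missing)}")


def split_datasets(datasets: dict, spec: SplitSpec):
    """Split named scans into (train, validation, test) pools.

    ``datasets`` maps ids to ``(features, labels)`` pairs.  Scans named in
    ``spec.test_ids`` are held out whole; all other frames are pooled and
    split ``train_fraction`` / rest, stratified by class.  Returns
    ``((X_tr, y_tr), (X_val, y_val), {id: (X, y)})``.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    test = {k: v for k, v in datasets.items() if k in set(spec.test_ids)}
    pool = [v for k, v in datasets.items() if k not in set(spec.test_ids)]
    if not pool:
        raise ValueError("no training datasets left after holding out test ids")
    X = np.concatenate([np.asarray(f) for f, _ in pool])
    y = np.concatenate([np.asarray(l).ravel() for _, l in pool])
    if spec.train_fraction >= 1.0:
        return (X, y), (X[:0], y[:0]), test
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=spec.train_fraction, stratify=y, random_state=spec.seed
    )
    return (X_tr, y_tr), (X_val, y_val), test


def crop_central(
    frame: CenteredFrame,
    radius: int = 150,
    downsample: int = 1,
    circular: bool = True,
    log_transform: bool = True,
) -> np.ndarray:
    """Central crop of a recentred frame for the CNN.

    Returns the (2·radius+1)² block around the canvas centre — 301×301 for
    the default 150-pixel radius — with invalid pixels zeroed, pixels beyond
    the radius zeroed by a circular mask, optional block-mean downsampling
    (trailing rows/columns beyond a whole block are dropped), and a log1p
    transform to tame the direct beam's dynamic range.  Standardization is
    the trainer's job (statistics belong to the training set).
    """
    canvas_n = frame.pixels.shape[0]
    c = canvas_n // 2
    if radius > c:
        raise ValueError(f"radius {radius} exceeds the canvas half-size {c}")
    lo, hi = c - radius, c + radius + 1
    block = np.where(frame.valid_mask[lo:hi, lo:hi], frame.pixels[lo:hi, lo:hi], 0.0)
    if circular:
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        block = np.where(yy * yy + xx * xx <= radius * radius, block, 0.0)
    if downsample > 1:
        side = (block.shape[0] // downsample) * downsample
        block = block[:side, :side]
        m = side // downsample
        block = block.reshape(m, downsample, m, downsample).mean(axis=(1, 3))
    if log_transform:
        block = np.log1p(block)
    return block.astype(np.float32)


# --------------------------------------------------------------------------
# classifiers


class RIAClassifier:
    """FCNN or SVM over RIA profiles, with its scaler and config bundled."""

    def __init__(self, kind: str, config, scaler: FeatureScaler, model):
        self.kind = kind
        self.config = config
        self.scaler = scaler
        self.model = model

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(X)).astype(np.int8)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self.scaler.transform(X))

    def save(self, path) -> None:
        joblib.dump({"kind": self.kind, "config": self.config, "scaler": self.scaler, "model": self.model}, path)

    @classmethod
    def load(cls, path) -> "RIAClassifier":
        d = joblib.load(path)
        return cls(d["kind"], d["config"], d["scaler"], d["model"])


def train_fcnn(profiles: np.ndarray, labels: np.ndarray, config: FCNNConfig | None = None) -> RIAClassifier:
    """Fit the one-hidden-layer fully connected network on RIA profiles.

    Thirty tanh hidden units, softmax output trained on categorical
    cross-entropy with Adam (any first-order method serves; the loss is the
    contract, the optimizer is configuration).
    """
    config = config or FCNNConfig()
    labels = np.asarray(labels).ravel()
    _check_classes(labels)
    scaler = FeatureScaler().fit(profiles)
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="tanh",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    model.fit(scaler.transform(profiles), labels)
    return RIAClassifier("fcnn", config, scaler, model)


def train_svm(profiles: np.ndarray, labels: np.ndarray, config: SVMConfig | None = None) -> RIAClassifier:
    """Fit the RBF-kernel SVM on RIA profiles (probability outputs enabled
    so all classifiers expose per-class scores)."""
    config = config or SVMConfig()
    labels = np.asarray(labels).ravel()
    _check_classes(labels)
    scaler = FeatureScaler().fit(profiles)
    model = SVC(kernel="rbf", C=config.C, gamma=config.gamma, probability=True, random_state=config.seed)
    model.fit(scaler.transform(profiles), labels)
    return RIAClassifier("svm", config, scaler, model)


def tune_svm(
    profiles: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig | None = None,
) -> tuple[RIAClassifier, dict]:
    """Randomized hyperparameter search for the SVM: log-uniform
    C ∈ [0.1, 1000] and γ ∈ [1e-4, 1], ``search_budget`` draws, 3-fold CV on
    the training pool.  Returns the refitted best model and the best params
    (the defaults are already competitive; the search rarely helps)."""
    config = config or SVMConfig()
    labels = np.asarray(labels).ravel()
    _check_classes(labels)
    scaler = FeatureScaler().fit(profiles)
    search = RandomizedSearchCV(
        SVC(kernel="rbf", probability=True, random_state=config.seed),
        {"C": loguniform(1e-1, 1e3), "gamma": loguniform(1e-4, 1e0)},
        n_iter=config.search_budget,
        cv=3,
        random_state=config.seed,
        n_jobs=1,
    )
    search.fit(scaler.transform(profiles), labels)
    return RIAClassifier("svm", config, scaler, search.best_estimator_), search.best_params_


class CNNClassifier:
    """The convolutional classifier plus its crop geometry and scalar
    standardization statistics."""

    def __init__(self, config: CNNConfig, net: SmallCNN, mean: float, std: float):
        self.kind = "cnn"
        self.config = config
        self.net = net
        self.mean = mean
        self.std = std

    def _standardize(self, crops: np.ndarray) -> np.ndarray:
        return (np.asarray(crops, dtype=np.float32) - self.mean) / self.std

    def predict(self, crops: np.ndarray) -> np.ndarray:
        return self.net.predict(self._standardize(crops)).astype(np.int8)

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._standardize(crops))

    def save(self, path) -> None:
        path = Path(path)
        self.net.save(path.with_suffix(".npz"))
        joblib.dump({"kind": "cnn", "config": self.config, "mean": self.mean, "std": self.std,
                     "net_file": path.with_suffix(".npz").name}, path)

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        path = Path(path)
        d = joblib.load(path)
        net = SmallCNN.load(path.parent / d["net_file"])
        return cls(d["config"], net, d["mean"], d["std"])


def train_cnn(
    crops: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
    val_crops: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    n_classes: int = 4,
    verbose: bool = False,
) -> CNNClassifier:
    """Fit the six-convolution-layer network on central crops.

    ``crops`` are the (already log1p-transformed) outputs of
    :func:`crop_central`; scalar mean/std standardization is fitted here on
    the training crops.  Early stopping monitors validation loss when a
    validation set is provided.
    """
    config = config or CNNConfig()
    labels = np.asarray(labels).ravel()
    _check_classes(labels)
    crops = np.asarray(crops, dtype=np.float32)
    mean = float(crops.mean())
    std = float(crops.std()) or 1.0
    net = SmallCNN(
        input_hw=crops.shape[1:3],
        n_classes=n_classes,
        channels=config.channels,
        dropout=config.dropout,
        dense_units=config.dense_units,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
    )
    Xv = None if val_crops is None else (np.asarray(val_crops, np.float32) - mean) / std
    net.fit((crops - mean) / std, labels, Xv, val_labels, verbose=verbose)
    return CNNClassifier(config, net, mean, std)


def load_classifier(path):
    """Reload any saved classifier (dispatches on the stored kind)."""
    d = joblib.load(path)
    if d["kind"] == "cnn":
        return CNNClassifier.load(path)
    return RIAClassifier(d["kind"], d["config"], d["scaler"], d["model"])


def predict_map(classifier, features: np.ndarray, grid_shape: tuple[int, int]):
    """Predict one label per scan point, arranged on the grid, plus the
    per-class score grid (scores sum to 1 per frame).  Ties in the score
    vector break towards the lower class index (carbon < amorphous_ice <
    crystalline_ice < mixed)."""
    rows, cols = grid_shape
    if len(features) != rows * cols:
        raise ValueError(f"{len(features)} feature rows cannot fill a {rows}×{cols} grid")
    proba = classifier.predict_proba(features)
    idx = np.argmax(proba, axis=1)  # first maximum → lowest class wins ties
    classes = getattr(getattr(classifier, "model", None), "classes_", None)
    labels = (classes[idx] if classes is not None else idx).astype(np.int8)
    return labels.reshape(rows, cols), proba.reshape(rows, cols, -1)
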