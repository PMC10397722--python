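"""Dataset assembly, splitting, and the three model families.

Models share one contract: fit on a :class:`LabeledDataset`, predict
class-probability rows that sum to 1, and refuse inputs whose feature
fingerprint differs from the one they were trained on. The 1D-CNN is the
primary model; random forest and logistic regression are library-default
baselines.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from orthoclass.datamodel import ExpressionMatrix, SampleLabels
from orthoclass.nn import CNN1DNet

MODEL_KINDS = ("cnn1d", "random_forest", "logistic_regression")


class ClassifyError(ValueError):
    pass


def feature_fingerprint(feature_ids) -> str:
    """SHA-256 of the ordered feature gene ids."""
    return hashlib.sha256("\n".join(map(str, feature_ids)).encode()).hexdigest()


def one_hot_encode(labels, class_list) -> np.ndarray:
    """One-hot matrix with columns in ``class_list`` order; rows sum to 1."""
    index = {c: i for i, c in enumerate(class_list)}
    out = np.zeros((len(labels), len(class_list)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ClassifyError(f"label {lab!r} not in class list {list(class_list)}")
        out[i, index[lab]] = 1.0
    return out


@dataclass
class LabeledDataset:
    """Feature-aligned samples × F matrix plus labels and one-hot encoding."""

    X: np.ndarray  # (n_samples, F) in log10_tpm
    labels: list[str]
    classes: list[str]
    feature_ids: tuple
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_ids = tuple(self.feature_ids)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ClassifyError("X must be samples × features matching labels")
        if self.X.shape[1] != len(self.feature_ids):
            raise ClassifyError("feature_ids length must match X width")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ClassifyError(f"labels outside the class list: {sorted(unknown)}")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.X.shape[0])]
        self.onehot = one_hot_encode(self.labels, self.classes)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def fingerprint(self) -> str:
        return feature_fingerprint(self.feature_ids)

    def subset(self, indices) -> "LabeledDataset":
        indices = list(indices)
        return LabeledDataset(
            X=self.X[indices],
            labels=[self.labels[i] for i in indices],
            classes=list(self.classes),
            feature_ids=self.feature_ids,
            sample_ids=[self.sample_ids[i] for i in indices],
        )


def make_dataset(
    matrix: ExpressionMatrix, labels: SampleLabels, classes: list[str] | None = None
) -> LabeledDataset:
    """Assemble a dataset from a log10-TPM matrix and sample labels."""
    if matrix.unit != "log10_tpm":
        raise ClassifyError(f"expected unit 'log10_tpm', got {matrix.unit!r}")
    y = labels.for_samples(matrix.sample_ids)
    if classes is None:
        classes = sorted(set(y))
    return LabeledDataset(
        X=matrix.values.T,
        labels=y,
        classes=list(classes),
        feature_ids=tuple(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
    )


@dataclass
class SplitSpec:
    """Train/validation/test fractions (default 80/10/10), seeded, stratified."""

    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(self.fractions) != 3 or any(not (0 < f < 1) for f in self.fractions):
            raise ClassifyError("fractions must be three values in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ClassifyError(f"fractions sum to {sum(self.fractions)!r}, expected 1")


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition into (train, val, test) per the spec; deterministic under seed.

    Partition sizes are the rounded fractions of the sample count; stratified
    mode keeps class proportions within ±1 sample per class per partition.
    """
    n = dataset.n_samples
    if n < len(dataset.classes):
        raise ClassifyError("fewer samples than classes")
    if spec.stratified:
        counts = {c: dataset.labels.count(c) for c in set(dataset.labels)}
        small = [c for c, k in counts.items() if k < 3]
        if small:
            raise ClassifyError(
                f"class {small[0]!r} has {counts[small[0]]} sample(s); stratified "
                "splitting needs >= 3 per class"
            )
    n_test = max(1, round(n * spec.fractions[2]))
    n_val = max(1, round(n * spec.fractions[1]))
    y = dataset.labels
    idx = np.arange(n)
    strat = y if spec.stratified else None
    rest, test_idx = train_test_split(
        idx, test_size=n_test, stratify=strat, random_state=spec.seed
    )
    strat_rest = [y[i] for i in rest] if spec.stratified else None
    train_idx, val_idx = train_test_split(
        rest, test_size=n_val, stratify=strat_rest, random_state=spec.seed
    )
    return (
        dataset.subset(np.sort(train_idx)),
        dataset.subset(np.sort(val_idx)),
        dataset.subset(np.sort(test_idx)),
    )


@dataclass
class ModelSpec:
    """Model family and (for the CNN) the architecture hyperparameters.

    The CNN interior defaults to two conv blocks (32 then 64 filters, kernel
    16, stride 1, max-pool 4, ReLU), dropout 0.3, a 128-unit dense layer and
    a softmax head, trained with Adam at 1e-3, batch 32, early-stopping
    patience 5 over at most 50 epochs. All of it is overridable; the interior
    is an explicit artifact decision, not an inherited one.
    """

    kind: str = "cnn1d"
    conv_filters: tuple = (32, 64)
    kernel_size: int = 16
    stride: int = 1
    pool_size: int = 4
    dropout: float = 0.3
    dense_units: int = 128
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ClassifyError(f"unknown model kind {self.kind!r}; use {MODEL_KINDS}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "conv_filters": list(self.conv_filters),
            "kernel_size": self.kernel_size,
            "stride": self.stride,
            "pool_size": self.pool_size,
            "dropout": self.dropout,
            "dense_units": self.dense_units,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "patience": self.patience,
            "seed": self.seed,
        }


@dataclass
class TrainedModel:
    """An opaque fitted predictor plus the metadata needed to use it safely."""

    kind: str
    predictor: object
    classes: list[str]
    feature_ids: tuple
    spec: ModelSpec
    metadata: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> str:
        return feature_fingerprint(self.feature_ids)


def train_model(
    spec: ModelSpec, train: LabeledDataset, val: LabeledDataset | None = None
) -> TrainedModel:
    """Fit one model family on the training partition.

    The CNN uses the validation partition for early stopping on validation
    loss (falling back to the training partition if none is given); random
    forest and logistic regression are the library defaults, seeded, and
    ignore ``val`` except for the reported validation accuracy.
    """
    if train.n_samples == 0:
        raise ClassifyError("empty training partition")
    k = len(train.classes)
    if k < 2:
        raise ClassifyError(f"need at least 2 classes, got {k}")
    if val is not None and (
        val.classes != train.classes or val.feature_ids != train.feature_ids
    ):
        raise ClassifyError("train/val must share class list and feature space")

    y_idx = np.array([train.classes.index(lab) for lab in train.labels])
    metadata = {"seed": spec.seed, "n_train": train.n_samples}
    if spec.kind == "cnn1d":
        net = CNN1DNet(
            n_features=train.n_features,
            n_classes=k,
            conv_filters=spec.conv_filters,
            kernel_size=spec.kernel_size,
            stride=spec.stride,
            pool_size=spec.pool_size,
            dropout=spec.dropout,
            dense_units=spec.dense_units,
            seed=spec.seed,
        )
        v = val if val is not None else train
        history = net.fit(
            train.X,
            train.onehot,
            v.X,
            v.onehot,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            patience=spec.patience,
        )
        metadata["epochs_run"] = history["epochs_run"]
        metadata["best_epoch"] = history["best_epoch"]
        predictor = net
    elif spec.kind == "random_forest":
        predictor = RandomForestClassifier(random_state=spec.seed)
        predictor.fit(train.X, y_idx)
    else:  # logistic_regression
        predictor = LogisticRegression(random_state=spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            predictor.fit(train.X, y_idx)

    model = TrainedModel(
        kind=spec.kind,
        predictor=predictor,
        classes=list(train.classes),
        feature_ids=train.feature_ids,
        spec=spec,
        metadata=metadata,
    )
    if val is not None and val.n_samples:
        _, pred = predict(model, val)
        metadata["val_accuracy"] = float(
            np.mean([p == t for p, t in zip(pred, val.labels)])
        )
    return model


def _proba_matrix(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    k = len(model.classes)
    if model.kind == "cnn1d":
        return model.predictor.predict_proba(x)
    raw = model.predictor.predict_proba(x)
    # sklearn columns follow predictor.classes_ (integer class indices seen
    # in training); expand to full K width in model.classes order
    out = np.zeros((x.shape[0], k))
    for col, cls_idx in enumerate(model.predictor.classes_):
        out[:, int(cls_idx)] = raw[:, col]
    return out


def predict(model: TrainedModel, data) -> tuple[np.ndarray, list[str]]:
    """Predict (probabilities, labels) for a feature-aligned input.

    ``data`` may be an :class:`ExpressionMatrix` in log10_tpm (genes ×
    samples), a :class:`LabeledDataset`, or a bare samples × F array. Inputs
    carrying feature ids are fingerprint-checked against the model; a
    mismatch is an error, not a silent misprediction. Ties in the argmax are
    broken by class-list order.
    """
    if isinstance(data, ExpressionMatrix):
        if data.unit != "log10_tpm":
            raise ClassifyError(f"expected unit 'log10_tpm', got {data.unit!r}")
        fp = feature_fingerprint(data.gene_ids)
        x = data.values.T
    elif isinstance(data, LabeledDataset):
        fp = data.fingerprint()
        x = data.X
    else:
        x = np.asarray(data, dtype=float)
        fp = None
    if fp is not None and fp != model.fingerprint:
        raise ClassifyError(
            f"feature fingerprint mismatch: model expects {len(model.feature_ids)} "
            f"features ({model.fingerprint[:12]}…), got {x.shape[1]} ({fp[:12]}…); "
            "project the matrix onto the model's feature space first"
        )
    if x.shape[1] != len(model.feature_ids):
        raise ClassifyError(
            f"input has {x.shape[1]} features, model expects {len(model.feature_ids)}"
        )
    proba = _proba_matrix(model, x)
    labels = [model.classes[i] for i in np.argmax(proba, axis=1)]
    return proba, labels


def save_model(model: TrainedModel, path) -> None:
    """Persist a model directory: predictor blob, class list, fingerprint, spec."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "kind": model.kind,
            "predictor": model.predictor,
            "classes": model.classes,
            "feature_ids": list(model.feature_ids),
            "metadata": model.metadata,
        },
        path / "model.joblib",
    )
    (path / "classes.json").write_text(json.dumps(model.classes))
    (path / "fingerprint.txt").write_text(model.fingerprint + "\n")
    (path / "modelspec.json").write_text(json.dumps(model.spec.to_dict(), indent=1))


def load_model(path) -> TrainedModel:
    """Load a saved model directory; verifies the stored fingerprint."""
    path = Path(path)
    fp_file = path / "fingerprint.txt"
    if not fp_file.exists():
        raise ClassifyError(f"{path}: fingerprint file missing")
    try:
        blob = joblib.load(path / "model.joblib")
        spec = ModelSpec(**json.loads((path / "modelspec.json").read_text()))
    except ClassifyError:
        raise
    except Exception as exc:  # corrupted payload must fail loudly
        raise ClassifyError(f"{path}: cannot load model ({exc})") from exc
    if "conv_filters" in spec.to_dict():
        spec.conv_filters = tuple(spec.conv_filters)
    model = TrainedModel(
        kind=blob["kind"],
        predictor=blob["predictor"],
        classes=list(blob["classes"]),
        feature_ids=tuple(blob["feature_ids"]),
        spec=spec,
        metadata=dict(blob.get("metadata", {})),
    )
    stored = fp_file.read_text().strip()
    if stored != model.fingerprint:
        raise ClassifyError(
            f"{path}: stored fingerprint does not match the model's feature ids"
        )
    return model
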