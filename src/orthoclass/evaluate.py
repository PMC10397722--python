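"""Multiclass metrics and the cross-species evaluation harness.

Per-class precision/recall/F1 come straight from the confusion matrix; the
weighted averages use true-class supports as weights, which makes weighted
recall algebraically identical to accuracy. Zero-division convention: a class
never predicted gets precision 0, a class never true gets recall 0 (logged),
and zero-support classes contribute nothing to the weighted averages — that
is what makes a 100% weighted precision with sub-100% recall arithmetically
possible when some model classes are absent from the evaluation cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from orthoclass.classify import TrainedModel, predict
from orthoclass.datamodel import ExpressionMatrix, SampleLabels
from orthoclass.orthology import FeatureSpace, project_to_feature_space

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise EvaluationError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise EvaluationError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion_matrix(true_labels, predicted_labels, class_list) -> ConfusionMatrix:
    """Tally entry (i, j) = samples with true class i predicted as class j."""
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError(
            f"label vectors differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    index = {c: i for i, c in enumerate(class_list)}
    unknown = [l for l in list(true_labels) + list(predicted_labels) if l not in index]
    if unknown:
        raise EvaluationError(f"label {unknown[0]!r} not in class list")
    counts = np.zeros((len(class_list), len(class_list)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(class_list))


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision, recall, F1 and support from TP/FP/FN tallies."""
    counts = cm.counts
    out = {}
    for i, c in enumerate(cm.classes):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        if tp + fp == 0:
            precision = 0.0
            if tp + fn > 0:
                logger.warning("class %r never predicted; precision set to 0", c)
        else:
            precision = tp / (tp + fp)
        recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
        f1 = f1_from_pr(precision, recall)
        out[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": tp + fn,
        }
    return out


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic combination 2·(R×P)/(R+P); defined as 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise EvaluationError("precision and recall must be in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def weighted_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """Support-weighted (precision, recall, F1) and accuracy.

    Classes with zero support are excluded from the weighting, so weighted
    recall equals accuracy on every confusion matrix.
    """
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    per = per_class_metrics(cm)
    support = np.array([per[c]["support"] for c in cm.classes], dtype=float)
    total = support.sum()
    weights = support / total
    precision_w = float(sum(w * per[c]["precision"] for w, c in zip(weights, cm.classes)))
    recall_w = float(sum(w * per[c]["recall"] for w, c in zip(weights, cm.classes)))
    f1_w = float(sum(w * per[c]["f1"] for w, c in zip(weights, cm.classes)))
    accuracy = float(np.trace(cm.counts) / cm.total)
    return precision_w, recall_w, f1_w, accuracy


@dataclass
class ClassificationReport:
    """Per-class and weighted metrics plus the underlying confusion matrix."""

    cm: ConfusionMatrix
    per_class: dict = field(default_factory=dict)
    precision_weighted: float = 0.0
    recall_weighted: float = 0.0
    f1_weighted: float = 0.0
    accuracy: float = 0.0

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, class_list) -> "ClassificationReport":
        cm = confusion_matrix(true_labels, predicted_labels, class_list)
        p, r, f1, acc = weighted_metrics(cm)
        return cls(
            cm=cm,
            per_class=per_class_metrics(cm),
            precision_weighted=p,
            recall_weighted=r,
            f1_weighted=f1,
            accuracy=acc,
        )

    def to_dict(self) -> dict:
        return {
            "classes": self.cm.classes,
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": self.per_class,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "accuracy": self.accuracy,
        }

    def display(self) -> str:
        """Table-style rendering: percentages to 1 decimal, F1 to 3 decimals."""
        lines = [
            f"precision\t{100 * self.precision_weighted:.1f}%",
            f"recall\t{100 * self.recall_weighted:.1f}%",
            f"F1-score\t{self.f1_weighted:.3f}",
            f"accuracy\t{100 * self.accuracy:.1f}%",
        ]
        return "\n".join(lines)


@dataclass
class LabelMap:
    """Total mapping from source labels to evaluation labels.

    Used both to translate target-species labels into model classes (e.g.
    HGG → GBM) and, in grade-agnostic mode, to collapse grades on both the
    true and the predicted side (e.g. {HGG, LGG, GBM} → glioma).
    """

    mapping: dict

    def apply(self, labels) -> list[str]:
        missing = [l for l in labels if l not in self.mapping]
        if missing:
            raise EvaluationError(f"unmapped label {missing[0]!r}")
        return [self.mapping[l] for l in labels]

    def apply_partial(self, labels) -> list[str]:
        """Map labels that have an entry; pass others through unchanged."""
        return [self.mapping.get(l, l) for l in labels]


def cross_species_evaluate(
    model: TrainedModel,
    target_matrix: ExpressionMatrix,
    target_labels: SampleLabels,
    feature_space: FeatureSpace,
    label_map: LabelMap | None = None,
    all_model_classes: bool = False,
) -> ClassificationReport:
    """Project a target-species cohort onto the model's features and score it.

    The label map must cover every target label; it is also applied (where it
    has entries) to the predicted labels, so a grade-collapsing map counts
    any within-group prediction as correct. By default the report's class
    universe is the classes with nonzero mapped support plus all predicted
    classes; ``all_model_classes=True`` scores over the full model class
    list instead.
    """
    projected = project_to_feature_space(target_matrix, feature_space)
    if projected.unit == "tpm":
        raise EvaluationError("target matrix must be log10_tpm before evaluation")
    fp_ids = tuple(feature_space.human_ids)
    if fp_ids != model.feature_ids:
        raise EvaluationError(
            "feature space does not match the model's training features"
        )
    _, predicted = predict(model, projected)
    true = target_labels.for_samples(projected.sample_ids)
    if label_map is not None:
        true = label_map.apply(true)
        predicted = label_map.apply_partial(predicted)
    if all_model_classes:
        universe = list(dict.fromkeys(list(model.classes) + sorted(set(true + predicted))))
    else:
        mapped_model = (
            label_map.apply_partial(model.classes) if label_map else list(model.classes)
        )
        present = set(true) | set(predicted)
        universe = [c for c in dict.fromkeys(mapped_model) if c in present]
        universe += sorted(present - set(universe))
    return ClassificationReport.from_labels(true, predicted, universe)
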