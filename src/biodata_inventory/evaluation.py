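"""Dataset splitting, classification metrics, entity-level NER metrics.

Classification metrics are the standard precision/recall/F1 over a
confusion matrix. NER is scored with partial-match entity-level metrics:
a predicted entity is credited when it overlaps at least one token of a
gold entity of the same kind, each gold entity crediting at most one
prediction (greedy left-to-right pairing).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .exceptions import UndefinedMetricError, ValidationError

#: an entity is a half-open token span plus its name kind
Span = tuple[int, int]
Entity = tuple[Span, str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions and the shuffling seed."""

    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.validation, self.test) < 0:
            raise ValueError("split fractions must be non-negative")


def split_dataset(items: Sequence, spec: SplitSpec = SplitSpec()) -> tuple[list, list, list]:
    """Random unstratified split into train/validation/test.

    Sizes are ``floor(train * n)`` and ``floor(validation * n)``, with the
    rounding remainder going to the test set (1587 items at 70/15/15
    gives 1110/238/239). Deterministic under ``spec.seed``.
    """
    if len(items) < 3:
        raise ValueError("need at least 3 items to split")
    order = list(items)
    random.Random(spec.seed).shuffle(order)
    n = len(order)
    n_train = int(spec.train * n)
    n_val = int(spec.validation * n)
    return (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )


def classification_metrics(counts: ConfusionCounts) -> MetricSet:
    """Precision, recall, and their harmonic mean F1.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R).
    A zero denominator raises :class:`UndefinedMetricError` rather than
    silently returning 0, since silent zeros corrupt model selection.
    """
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive gold labels")
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision and recall both zero")
    f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(precision, recall, f1)


def confusion_from_labels(gold: Iterable, predicted: Iterable) -> ConfusionCounts:
    """Tally a confusion matrix from parallel binary label vectors.

    Labels are truthy for the positive class (1/True/"positive").
    """

    def as_bool(x) -> bool:
        return x in (1, True, "positive")

    tp = fp = tn = fn = 0
    gold, predicted = list(gold), list(predicted)
    if len(gold) != len(predicted):
        raise ValidationError("gold and predicted label vectors differ in length")
    for g, p in zip(gold, predicted):
        g, p = as_bool(g), as_bool(p)
        if g and p:
            tp += 1
        elif not g and p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def safe_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Like :func:`classification_metrics` but mapping undefined to None.

    Used inside training loops where an early epoch may predict no
    positives at all; None never wins checkpoint selection.
    """
    try:
        ms = classification_metrics(counts)
        return {"precision": ms.precision, "recall": ms.recall, "f1": ms.f1}
    except UndefinedMetricError:
        return {"precision": None, "recall": None, "f1": None}


def bio_label_spans(labels: Sequence[str]) -> list[Entity]:
    """Decode a plain BIO label sequence into half-open entity spans.

    Follows the same lenient semantics as mention decoding: an orphan
    I-X opens a new span, B-X after B-X closes the first.
    """
    spans: list[Entity] = []
    start: int | None = None
    kind: str | None = None
    for i, label in enumerate(labels):
        if label == "O":
            if start is not None:
                spans.append(((start, i), kind))
                start, kind = None, None
            continue
        prefix, _, suffix = label.partition("-")
        k = "common" if suffix == "COM" else "full"
        if prefix == "B" or k != kind:
            if start is not None:
                spans.append(((start, i), kind))
            start, kind = i, k
    if start is not None:
        spans.append(((start, len(labels)), kind))
    return spans


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def ner_partial_metrics(gold: Sequence[Entity], predicted: Sequence[Entity]) -> MetricSet:
    """Partial-match entity-level precision/recall/F1.

    A predicted entity counts as a true positive iff it overlaps >= 1
    token of a gold entity of the same kind; pairing is greedy
    left-to-right (both lists sorted by span) and each gold entity
    credits at most one prediction. Precision is over predicted
    entities, recall over gold entities.
    """
    gold_sorted = sorted(gold)
    pred_sorted = sorted(predicted)
    matched_gold: set[int] = set()
    tp = 0
    for span, kind in pred_sorted:
        for gi, (gspan, gkind) in enumerate(gold_sorted):
            if gi in matched_gold or gkind != kind:
                continue
            if _overlaps(span, gspan):
                matched_gold.add(gi)
                tp += 1
                break
    return classification_metrics(
        ConfusionCounts(tp=tp, fp=len(pred_sorted) - tp, fn=len(gold_sorted) - tp)
    )


def agreement(labels_a: Mapping[Hashable, object], labels_b: Mapping[Hashable, object]) -> float:
    """Inter-annotator agreement: fraction of ids with equal labels."""
    if set(labels_a) != set(labels_b):
        raise ValidationError("annotator label sets cover different article ids")
    if not labels_a:
        raise ValidationError("no labels to compare")
    equal = sum(1 for k, v in labels_a.items() if labels_b[k] == v)
    return equal / len(labels_a)


def select_model(
    validation_metrics: Mapping[str, MetricSet] | Sequence[tuple[str, MetricSet]],
    task: str,
) -> str:
    """Pick the best model on validation metrics.

    Classification models compete on precision, NER models on F1. Ties
    resolve to the first listed model with a warning.
    """
    if task == "classification":
        key = lambda ms: ms.precision  # noqa: E731
    elif task == "ner":
        key = lambda ms: ms.f1  # noqa: E731
    else:
        raise ValueError(f"unknown task {task!r}")
    pairs = list(validation_metrics.items()) if isinstance(validation_metrics, Mapping) else list(validation_metrics)
    if not pairs:
        raise ValueError("no models to select from")
    best_id, best_val = pairs[0][0], key(pairs[0][1])
    tied = False
    for model_id, ms in pairs[1:]:
        val = key(ms)
        if val > best_val:
            best_id, best_val, tied = model_id, val, False
        elif val == best_val:
            tied = True
    if tied:
        warnings.warn(
            f"model selection tie at {best_val:.4f}; keeping first listed ({best_id})",
            stacklevel=2,
        )
    return best_id
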