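"""Model backends: a deterministic rule backend and trainable linear models.

Every stage of the pipeline talks to a :class:`~biodata_inventory.extraction.ModelBackend`
(``classify`` + ``tag``), so model weights are never required to run or
test the pipeline itself:

* :class:`RuleBackend` classifies by cue-phrase lookup and tags by
  longest-match dictionary lookup of known names with configured
  per-name probabilities. It is the offline stand-in used throughout the
  test suite and by the synthetic end-to-end runs.
* :class:`LinearArticleClassifier` / :class:`LinearTokenTagger` are
  scikit-learn-style estimators (TF-IDF + SGD logistic regression, and
  hashed token-window features + SGD respectively) trained epoch by
  epoch through :func:`finetune`, which records per-epoch validation
  metrics and keeps the checkpoint maximizing precision (classification)
  or entity-level F1 (tagging).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction import DictVectorizer
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import SGDClassifier

from .records import BIO_LABELS, ClassificationResult, NameKind, TokenPrediction

#: cue phrases whose presence marks an abstract as describing a resource
DEFAULT_CUES = (
    "freely available at",
    "publicly available at",
    "can be accessed at",
    "database of",
    "data resource for",
)

_PUNCT_EDGES = "()[]{}\"'.,;:!?"
_TOKEN_RE = re.compile(r"\S+")


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with surrounding punctuation trimmed.

    Tokens reduced to nothing by trimming (bare punctuation) are kept as
    their original text so word indices stay aligned with the input.
    """
    tokens = []
    for match in _TOKEN_RE.finditer(text):
        stripped = match.group(0).strip(_PUNCT_EDGES)
        tokens.append(stripped if stripped else match.group(0))
    return tokens


class RuleBackend:
    """Deterministic fixture backend: cue phrases + name dictionary.

    ``name_dict`` maps a name surface string to ``(kind, prob)`` where
    ``prob`` is either one probability shared by every token of the name
    or a per-token sequence. Tagging scans the token stream left to
    right taking the longest dictionary match at each position.
    """

    def __init__(
        self,
        name_dict: Mapping[str, tuple[NameKind, float | Sequence[float]]] | None = None,
        cues: Sequence[str] = DEFAULT_CUES,
        positive_score: float = 0.99,
        negative_score: float = 0.01,
        o_prob: float = 0.999,
    ):
        self.cues = tuple(c.lower() for c in cues)
        self.positive_score = positive_score
        self.negative_score = negative_score
        self.o_prob = o_prob
        self._entries: dict[tuple[str, ...], tuple[NameKind, tuple[float, ...]]] = {}
        self._max_len = 0
        for name, (kind, prob) in (name_dict or {}).items():
            toks = tuple(tokenize(name))
            probs = (
                tuple(prob) if isinstance(prob, (list, tuple)) else (float(prob),) * len(toks)
            )
            if len(probs) != len(toks):
                raise ValueError(f"per-token probs for {name!r} do not match token count")
            self._entries[toks] = (kind, probs)
            self._max_len = max(self._max_len, len(toks))

    def classify(self, text: str) -> ClassificationResult:
        lowered = text.lower()
        if any(cue in lowered for cue in self.cues):
            return ClassificationResult("positive", self.positive_score)
        return ClassificationResult("negative", self.negative_score)

    def tag(self, text: str) -> list[TokenPrediction]:
        tokens = tokenize(text)
        preds: list[TokenPrediction] = []
        i = 0
        while i < len(tokens):
            matched = False
            for length in range(min(self._max_len, len(tokens) - i), 0, -1):
                window = tuple(tokens[i : i + length])
                entry = self._entries.get(window)
                if entry is None:
                    continue
                kind, probs = entry
                suffix = "COM" if kind == "common" else "FUL"
                for j in range(length):
                    label = f"{'B' if j == 0 else 'I'}-{suffix}"
                    preds.append(TokenPrediction(tokens[i + j], i + j, label, probs[j]))
                i += length
                matched = True
                break
            if not matched:
                preds.append(TokenPrediction(tokens[i], i, "O", self.o_prob))
                i += 1
        return preds


# ---------------------------------------------------------------------------
# trainable backends
# ---------------------------------------------------------------------------


def select_checkpoint(history: Sequence[Mapping[str, float | None]], metric: str) -> int:
    """Return the index of the epoch maximizing ``metric``.

    ``history`` holds one mapping per epoch; a missing/None value (e.g.
    an undefined precision when no positives were predicted) scores
    below any defined value. Ties resolve to the earliest epoch.
    """
    if not history:
        raise ValueError("empty training history")
    best_idx, best_val = 0, -1.0
    for idx, entry in enumerate(history):
        value = entry.get(metric)
        score = -1.0 if value is None else float(value)
        if score > best_val:
            best_idx, best_val = idx, score
    return best_idx


class LinearArticleClassifier(BaseEstimator, ClassifierMixin):
    """TF-IDF + SGD logistic-regression article classifier.

    Trained one epoch at a time; when validation data is supplied to
    :meth:`fit`, per-epoch precision/recall/F1 are recorded in
    ``history_`` and the coefficient snapshot with the highest validation
    precision is restored afterwards (``best_epoch_``).
    """

    def __init__(self, max_epochs: int = 10, alpha: float = 1e-5, random_state: int = 0):
        self.max_epochs = max_epochs
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        from .evaluation import confusion_from_labels, safe_metrics

        y = np.asarray(y)
        self.vectorizer_ = TfidfVectorizer(lowercase=True, ngram_range=(1, 2))
        Xt = self.vectorizer_.fit_transform(X)
        self.classes_ = np.unique(y)
        sgd = SGDClassifier(
            loss="log_loss", alpha=self.alpha, random_state=self.random_state
        )
        rng = np.random.RandomState(self.random_state)
        self.history_ = []
        snapshots = []
        order = np.arange(Xt.shape[0])
        for epoch in range(self.max_epochs):
            rng.shuffle(order)
            sgd.partial_fit(Xt[order], y[order], classes=self.classes_)
            if validation_data is not None:
                Xv, yv = validation_data
                pred = sgd.predict(self.vectorizer_.transform(Xv))
                metrics = safe_metrics(confusion_from_labels(yv, pred))
                metrics["epoch"] = epoch
                self.history_.append(metrics)
                snapshots.append(copy.deepcopy(sgd))
        if snapshots:
            self.best_epoch_ = select_checkpoint(self.history_, "precision")
            self.estimator_ = snapshots[self.best_epoch_]
        else:
            self.best_epoch_ = self.max_epochs - 1
            self.estimator_ = sgd
        return self

    def predict(self, X):
        return self.estimator_.predict(self.vectorizer_.transform(X))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self.vectorizer_.transform(X))

    def classify(self, text: str) -> ClassificationResult:
        proba = self.predict_proba([text])[0]
        pos_idx = list(self.estimator_.classes_).index(1)
        score = float(proba[pos_idx])
        return ClassificationResult("positive" if score >= 0.5 else "negative", score)

    def tag(self, text: str) -> list[TokenPrediction]:
        raise NotImplementedError("classification backend does not tag tokens")


def _token_features(tokens: Sequence[str], i: int) -> dict[str, str | bool]:
    tok = tokens[i]
    return {
        "lower": tok.lower(),
        "istitle": tok.istitle(),
        "isupper": tok.isupper(),
        "hasdigit": any(c.isdigit() for c in tok),
        "suffix3": tok[-3:].lower(),
        "prefix3": tok[:3].lower(),
        "prev": tokens[i - 1].lower() if i > 0 else "<s>",
        "next": tokens[i + 1].lower() if i + 1 < len(tokens) else "</s>",
    }


class LinearTokenTagger(BaseEstimator):
    """Token-window features + SGD logistic regression BIO tagger.

    ``fit`` takes token sequences with their BIO label sequences; with
    validation data it records per-epoch entity-level partial-match
    metrics and restores the checkpoint with the highest F1.
    """

    def __init__(self, max_epochs: int = 10, alpha: float = 1e-5, random_state: int = 0):
        self.max_epochs = max_epochs
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, sentences, labels, validation_data=None):
        from .evaluation import bio_label_spans, ner_partial_metrics

        feats = [
            _token_features(sent, i) for sent in sentences for i in range(len(sent))
        ]
        flat_labels = np.array([lab for seq in labels for lab in seq])
        self.vectorizer_ = DictVectorizer()
        Xt = self.vectorizer_.fit_transform(feats)
        sgd = SGDClassifier(
            loss="log_loss", alpha=self.alpha, random_state=self.random_state
        )
        rng = np.random.RandomState(self.random_state)
        classes = np.array(sorted(set(flat_labels) | {"O"}))
        self.history_ = []
        snapshots = []
        order = np.arange(Xt.shape[0])
        for epoch in range(self.max_epochs):
            rng.shuffle(order)
            sgd.partial_fit(Xt[order], flat_labels[order], classes=classes)
            if validation_data is not None:
                val_sents, val_labels = validation_data
                gold, pred = [], []
                for sent, lab in zip(val_sents, val_labels):
                    gold.extend(bio_label_spans(lab))
                    pred.extend(bio_label_spans(self._predict_labels(sent, sgd)))
                try:
                    ms = ner_partial_metrics(gold, pred)
                    metrics = {
                        "precision": ms.precision,
                        "recall": ms.recall,
                        "f1": ms.f1,
                    }
                except Exception:
                    metrics = {"precision": None, "recall": None, "f1": None}
                metrics["epoch"] = epoch
                self.history_.append(metrics)
                snapshots.append(copy.deepcopy(sgd))
        if snapshots:
            self.best_epoch_ = select_checkpoint(self.history_, "f1")
            self.estimator_ = snapshots[self.best_epoch_]
        else:
            self.best_epoch_ = self.max_epochs - 1
            self.estimator_ = sgd
        return self

    def _predict_labels(self, tokens, estimator=None) -> list[str]:
        est = estimator if estimator is not None else self.estimator_
        if not tokens:
            return []
        feats = [_token_features(tokens, i) for i in range(len(tokens))]
        return list(est.predict(self.vectorizer_.transform(feats)))

    def tag(self, text: str) -> list[TokenPrediction]:
        tokens = tokenize(text)
        if not tokens:
            return []
        feats = [_token_features(tokens, i) for i in range(len(tokens))]
        Xt = self.vectorizer_.transform(feats)
        proba = self.estimator_.predict_proba(Xt)
        classes = list(self.estimator_.classes_)
        preds = []
        for i, tok in enumerate(tokens):
            j = int(np.argmax(proba[i]))
            label = classes[j]
            if label not in BIO_LABELS:
                label = "O"
            preds.append(TokenPrediction(tok, i, label, float(proba[i][j])))
        return preds

    def classify(self, text: str) -> ClassificationResult:
        raise NotImplementedError("tagging backend does not classify articles")


class CompositeBackend:
    """Combine a classification backend and a tagging backend into one."""

    def __init__(self, classifier, tagger):
        self.classifier = classifier
        self.tagger = tagger

    def classify(self, text: str) -> ClassificationResult:
        return self.classifier.classify(text)

    def tag(self, text: str) -> list[TokenPrediction]:
        return self.tagger.tag(text)


@dataclass
class FinetuneSpec:
    """Model name + hyperparameters for :func:`finetune`.

    ``model`` is informational (the estimator family is fixed);
    hyperparameters not listed fall back to estimator defaults.
    """

    task: str  # "classification" | "ner"
    model: str = "linear-sgd"
    max_epochs: int = 10
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)


def finetune(spec: FinetuneSpec, train, validation) -> LinearArticleClassifier | LinearTokenTagger:
    """Train a backend for at most ``spec.max_epochs`` epochs.

    Per-epoch validation metrics are recorded on the estimator's
    ``history_``; the checkpoint kept is the epoch maximizing validation
    precision for classification and entity-level F1 for tagging,
    regardless of epoch number. Deterministic for a fixed seed and data.
    """
    if spec.max_epochs > 10:
        raise ValueError("training is capped at 10 epochs")
    kwargs = dict(max_epochs=spec.max_epochs, random_state=spec.seed)
    kwargs.update(spec.hyperparams)
    if spec.task == "classification":
        est: LinearArticleClassifier | LinearTokenTagger = LinearArticleClassifier(**kwargs)
    elif spec.task == "ner":
        est = LinearTokenTagger(**kwargs)
    else:
        raise ValueError(f"unknown task {spec.task!r}")
    X, y = train
    est.fit(X, y, validation_data=validation)
    return est


def save_backend(backend, path: str | Path) -> Path:
    """Serialize a trained backend to disk (joblib format)."""
    path = Path(path)
    joblib.dump(backend, path)
    return path


def load_backend(path: str | Path):
    """Reload a backend serialized by :func:`save_backend`."""
    return joblib.load(Path(path))
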