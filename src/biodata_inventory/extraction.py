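"""Classification, BIO-span decoding, best-name selection, URL extraction.

The token tagger labels each (sub-word) token with one of five BIO labels
(B-COM, I-COM, B-FUL, I-FUL, O) distinguishing short "common" resource
names from expanded "full" names. :func:`decode_mentions` reassembles
those labels into name mentions whose confidence is the mean of the
member-token probabilities; :func:`select_best_names` then picks the
highest-confidence name of each kind and the best overall.
"""

from __future__ import annotations

import re
from statistics import fmean
from typing import Iterable, Protocol, Sequence

from .exceptions import InferenceError
from .records import (
    BestNames,
    ClassificationResult,
    Mention,
    NameKind,
    TokenPrediction,
)

#: punctuation stripped from the end of a decoded name or extracted URL
TRAILING_PUNCT = ".,;:!?\"')]}"

#: URLs must carry an http(s) scheme or start with "www."; the character
#: class excludes whitespace and closing delimiters so that a URL inside
#: parentheses or followed by sentence punctuation ends cleanly.
URL_RE = re.compile(r"(?:https?://|www\.)[^\s<>()\[\]{}\"']+", re.IGNORECASE)


class ModelBackend(Protocol):
    """Pluggable model contract: binary article classification + tagging.

    Implementations must be deterministic for a fixed model state and
    input text. See :mod:`biodata_inventory.backends` for the rule-based
    fixture backend and the trainable linear backends.
    """

    def classify(self, text: str) -> ClassificationResult: ...

    def tag(self, text: str) -> list[TokenPrediction]: ...


def classify_article(text: str, backend: ModelBackend) -> ClassificationResult:
    """Classify prepared title+abstract text as describing a resource or not.

    Backend failures surface as :class:`InferenceError`; for probabilistic
    backends the positive label corresponds to score >= 0.5.
    """
    if not text:
        raise ValueError("classification input text must be non-empty")
    try:
        return backend.classify(text)
    except Exception as exc:
        raise InferenceError(f"classification backend failed: {exc}") from exc


def _merge_words(preds: Sequence[TokenPrediction]) -> list[tuple[str, str, list[float]]]:
    """Collapse sub-word tokens sharing a word_index into whole words.

    Returns (word_text, label, member_probs) per word; the word takes the
    label of its first piece, while every piece's probability counts
    toward the mention mean.
    """
    words: list[tuple[str, str, list[float]]] = []
    last_index: int | None = None
    for pred in preds:
        piece = pred.token[2:] if pred.token.startswith("##") else pred.token
        if pred.word_index == last_index and words:
            text, label, probs = words[-1]
            words[-1] = (text + piece, label, probs + [pred.prob])
        else:
            words.append((piece, pred.label, [pred.prob]))
        last_index = pred.word_index
    return words


def decode_mentions(preds: Sequence[TokenPrediction]) -> list[Mention]:
    """Decode BIO token predictions into name mentions.

    A mention is a maximal run opening at ``B-X`` and continuing through
    ``I-X`` of the same kind. Lenient repairs: an orphan ``I-X`` (no
    preceding ``B-X`` of that kind) opens a new mention, and ``B-X``
    directly after a ``B-X`` closes the first and opens a second.
    Confidence is the arithmetic mean of all member-token probabilities;
    trailing punctuation is stripped from the text and mentions left
    empty by stripping are discarded.
    """
    words = _merge_words(preds)
    mentions: list[Mention] = []
    cur_words: list[str] = []
    cur_probs: list[float] = []
    cur_kind: NameKind | None = None

    def close() -> None:
        nonlocal cur_words, cur_probs, cur_kind
        if cur_kind is not None:
            text = " ".join(cur_words).rstrip(TRAILING_PUNCT).rstrip()
            if text:
                mentions.append(Mention(text, cur_kind, fmean(cur_probs)))
        cur_words, cur_probs, cur_kind = [], [], None

    for text, label, probs in words:
        if label == "O":
            close()
            continue
        prefix, _, suffix = label.partition("-")
        kind: NameKind = "common" if suffix == "COM" else "full"
        starts_new = prefix == "B" or kind != cur_kind
        if starts_new:
            close()
            cur_kind = kind
        cur_words.append(text)
        cur_probs.extend(probs)
    close()
    return mentions


def select_best_names(mentions: Iterable[Mention]) -> BestNames:
    """Pick the highest-confidence mention per kind and the best overall.

    The overall best name is whichever of the per-kind winners has the
    higher confidence; on an exact tie the common name wins (common
    names are the most reliably identified kind).
    """
    best_common: Mention | None = None
    best_full: Mention | None = None
    for mention in mentions:
        if mention.kind == "common":
            if best_common is None or mention.confidence > best_common.confidence:
                best_common = mention
        else:
            if best_full is None or mention.confidence > best_full.confidence:
                best_full = mention
    if best_common is None:
        best = best_full
    elif best_full is None:
        best = best_common
    else:
        best = best_full if best_full.confidence > best_common.confidence else best_common
    return BestNames(best_common=best_common, best_full=best_full, best_name=best)


def extract_urls(abstract: str) -> list[str]:
    """Extract distinct URLs from abstract text, in order of first appearance.

    Matches require an http(s) scheme or a leading ``www.``; trailing
    sentence punctuation and closing brackets are stripped.
    """
    seen: set[str] = set()
    urls: list[str] = []
    for match in URL_RE.finditer(abstract):
        url = match.group(0).rstrip(TRAILING_PUNCT)
        if url and url not in seen:
            seen.add(url)
            urls.append(url)
    return urls
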