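"""Domain types shared across the pipeline stages.

The pipeline moves articles through successively richer representations:
``ArticleRecord`` (raw corpus) -> ``ArticlePrediction`` (classifier + NER
output) -> ``CandidateRecord`` (positively classified, filtered) ->
``ResourceRecord`` (deduplicated inventory entry).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Literal

NameKind = Literal["common", "full"]

#: The five-value BIO label alphabet for resource-name tagging.
#: B-/I- prefixes mark the beginning/continuation of a span; COM and FUL
#: distinguish short "common" names (e.g. PDB) from expanded "full" names
#: (e.g. Protein Data Bank); O is outside any name.
BIO_LABELS = ("B-COM", "I-COM", "B-FUL", "I-FUL", "O")

#: Flags a resource record can carry into manual review.
FLAG_LOW_PROB = "low_prob"
FLAG_DUP_NAMES = "duplicate_names"
FLAG_DUP_URLS = "duplicate_urls"


@dataclass(frozen=True)
class Query:
    """A user-provided literature-API query expression."""

    text: str
    source_path: str | None = None


@dataclass
class ArticleRecord:
    """One publication as returned by the literature API."""

    pmid: str | None
    title: str
    abstract: str
    pub_date: str = ""
    language: str = ""
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pmid is not None and self.pmid == "":
            raise ValueError("pmid, when present, must be non-empty")
        if not isinstance(self.title, str) or not isinstance(self.abstract, str):
            raise TypeError("title and abstract must be strings")


@dataclass(frozen=True)
class TokenPrediction:
    """One token emitted by a token-classification backend.

    ``word_index`` groups sub-word pieces back into words; it is
    non-decreasing within a sequence.
    """

    token: str
    word_index: int
    label: str
    prob: float

    def __post_init__(self) -> None:
        if self.label not in BIO_LABELS:
            raise ValueError(f"unknown BIO label {self.label!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"token probability {self.prob} outside [0, 1]")


@dataclass(frozen=True)
class Mention:
    """A decoded resource-name span.

    ``confidence`` is the arithmetic mean of the probabilities of the
    tokens constituting the mention.
    """

    text: str
    kind: NameKind
    confidence: float

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("mention text must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class ClassificationResult:
    """Binary 'describes a biodata resource?' decision with a score."""

    label: Literal["positive", "negative"]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


@dataclass(frozen=True)
class BestNames:
    """Per-kind argmax mentions and the best overall name.

    ``best_name`` is whichever of ``best_common`` / ``best_full`` carries
    the higher confidence (common preferred on an exact tie).
    """

    best_common: Mention | None = None
    best_full: Mention | None = None
    best_name: Mention | None = None


@dataclass
class ArticlePrediction:
    """Classifier + NER output for one article, prior to filtering."""

    pmid: str | None
    classification: ClassificationResult
    mentions: list[Mention] = field(default_factory=list)
    urls: list[str] = field(default_factory=list)
    title_abstract: str = ""
    pub_date: str = ""

    @property
    def best_names(self) -> BestNames:
        from .extraction import select_best_names

        return select_best_names(self.mentions)


@dataclass
class CandidateRecord:
    """One positively classified article that survived the filters."""

    pmid: str | None
    best_names: BestNames
    urls: list[str]
    best_prob: float
    title_abstract: str = ""
    pub_date: str = ""


@dataclass
class ResourceRecord:
    """A deduplicated inventory entry."""

    resource_id: str
    best_name: str
    best_common: str | None
    best_full: str | None
    url: str
    url_key: str
    member_pmids: list[str]
    best_prob: float
    flags: set[str] = field(default_factory=set)
    latest_title_abstract: str = ""
    latest_date: str = ""
    urls: list[str] = field(default_factory=list)


def resource_id_for(best_name: str, url_key: str) -> str:
    """Stable identifier for a (best name, normalized URL) pair.

    Deterministic across runs and machines so that review files written
    against one build of the inventory remain valid for a rebuild.
    """
    digest = hashlib.sha1(f"{best_name}\t{url_key}".encode("utf-8")).hexdigest()
    return digest[:12]


@dataclass(frozen=True)
class ReviewDecision:
    """One curator decision about a flagged resource record."""

    resource_id: str
    action: str  # keep | remove | merge:<id> | partial_merge:<id>


@dataclass(frozen=True)
class UrlStatus:
    """Outcome of the three-attempt URL viability protocol."""

    url: str
    attempts: int
    status_code: int | None
    alive: bool
    checked_at: str = ""


@dataclass(frozen=True)
class GeoLocation:
    """A country assignment for a resource, from IP or affiliation text."""

    source: Literal["ip", "affiliation"]
    country: str
    alpha3: str
    lat: float | None = None
    lon: float | None = None
    provider: str = ""


@dataclass
class ArticleMetadata:
    """Per-article metadata retrieved for enrichment."""

    pmid: str
    affiliations: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    grant_ids: list[str] = field(default_factory=list)
    agencies: list[str] = field(default_factory=list)
    cited_by: int = 0

    def __post_init__(self) -> None:
        if self.cited_by < 0:
            raise ValueError("cited_by must be >= 0")


@dataclass(frozen=True)
class RegistryRecord:
    """One record from an external registry export (re3data, FAIRsharing)."""

    source: str
    name: str = ""
    url: str = ""
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name and not self.url:
            raise ValueError("registry record needs a name or a URL")
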