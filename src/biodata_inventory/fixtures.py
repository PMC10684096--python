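"""Synthetic corpora with known ground truth, and offline service clients.

The generator plants resource announcements (a full name, a common name
and 1-2 URLs woven into templated abstract sentences) among negative
abstracts that contain URLs but no resource-description cues, and
records exactly what it planted: per-article BIO labels, URLs, per-name
confidences, and the distinct resource set the pipeline should recover.
Together with :func:`fixture_services` — deterministic stand-ins for the
literature API, the HTTP checker, the web archive, geolocation
providers, and the article-metadata endpoint — the full pipeline runs
end to end with no network and a checkable right answer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .backends import RuleBackend, tokenize
from .corpus import prepare_text
from .inventory import normalize_url
from .records import ArticleRecord, GeoLocation, NameKind

# template vocabulary; kept disjoint from cue phrases used by negatives
_NAME_PARTS = [
    ("Geno", "Genome"),
    ("Prote", "Protein"),
    ("Chemo", "Chemical"),
    ("Immuno", "Immune"),
    ("Patho", "Pathogen"),
    ("Neuro", "Neural"),
    ("Metabo", "Metabolite"),
    ("Phyto", "Plant"),
    ("Myco", "Fungal"),
    ("Viro", "Viral"),
]
_NAME_SUFFIXES = [
    ("Base", "Knowledge Base"),
    ("Bank", "Data Bank"),
    ("Atlas", "Expression Atlas"),
    ("Hub", "Annotation Hub"),
    ("Vault", "Sequence Vault"),
]
_TOPICS = [
    "enzyme variants",
    "regulatory elements",
    "splice isoforms",
    "metabolic pathways",
    "structural motifs",
    "expression profiles",
    "orthologous groups",
    "epigenetic marks",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    ``noise_level`` is the probability that a planted resource's emitted
    model output is corrupted (its full name truncated and both name
    confidences dropped into [0.5, 0.95], below the review threshold).
    """

    n_articles: int = 200
    positive_fraction: float = 0.3
    name_vocab: Sequence[tuple[str, str]] | None = None
    url_templates: Sequence[str] = ("http://{slug}.example.org",)
    dup_pairs: int = 0
    multi_url_fraction: float = 0.0
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        for name, value in (
            ("positive_fraction", self.positive_fraction),
            ("multi_url_fraction", self.multi_url_fraction),
            ("noise_level", self.noise_level),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.name_vocab is not None and not self.name_vocab and self.positive_fraction > 0:
            raise ValueError("name_vocab is empty but positive_fraction > 0")


@dataclass
class PlantedResource:
    """One distinct resource the generator planted."""

    common: str
    full: str
    url: str
    urls: list[str]
    common_conf: float
    full_conf: float
    pmids: list[str] = field(default_factory=list)
    corrupted: bool = False

    @property
    def best_name(self) -> str:
        return self.common if self.common_conf >= self.full_conf else self.full


@dataclass
class PlantedArticle:
    """Ground truth for one generated article."""

    pmid: str
    is_positive: bool
    resource_index: int | None
    urls: list[str]
    mentions: list[tuple[str, NameKind, float]]
    bio_labels: list[str]


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact end-to-end checks."""

    resources: list[PlantedResource]
    articles: dict[str, PlantedArticle]
    name_dict: dict[str, tuple[NameKind, float]]

    def distinct_resource_keys(self) -> set[tuple[str, str]]:
        """The (best name, normalized URL) set the pipeline should yield."""
        return {(r.best_name, normalize_url(r.url)) for r in self.resources}


def _default_vocab(n: int) -> list[tuple[str, str]]:
    vocab = []
    k = 0
    while len(vocab) < n:
        for pre, pre_full in _NAME_PARTS:
            for suf, suf_full in _NAME_SUFFIXES:
                if k == 0:
                    vocab.append((f"{pre}{suf}", f"{pre_full} {suf_full}"))
                else:
                    vocab.append((f"{pre}{suf}{k}", f"{pre_full} {suf_full} {k}"))
                if len(vocab) >= n:
                    return vocab
        k += 1
    return vocab


def generate_corpus(spec: CorpusSpec) -> tuple[list[ArticleRecord], GroundTruth]:
    """Generate articles plus their ground truth, fully seed-determined.

    Positives embed one (common, full) name pair and 1-2 URLs in
    announcement-style abstracts; negatives contain a URL but none of
    the cue phrases the rule classifier keys on. ``dup_pairs`` resources
    receive a second article with a distinct PMID and a later date.
    """
    rng = random.Random(spec.seed)
    n_pos = round(spec.n_articles * spec.positive_fraction)
    n_resources = n_pos - spec.dup_pairs
    if n_pos > 0 and n_resources < 1:
        raise ValueError("dup_pairs too large for the number of positives")

    vocab = list(spec.name_vocab) if spec.name_vocab is not None else _default_vocab(n_resources)
    if n_resources > len(vocab):
        raise ValueError("name_vocab smaller than the number of planted resources")

    resources: list[PlantedResource] = []
    name_dict: dict[str, tuple[NameKind, float]] = {}
    for i in range(n_resources):
        common, full = vocab[i]
        slug = common.lower()
        urls = [spec.url_templates[i % len(spec.url_templates)].format(slug=slug)]
        if rng.random() < spec.multi_url_fraction:
            urls.append(f"http://mirror.{slug}.example.org")
        corrupted = rng.random() < spec.noise_level
        if corrupted:
            common_conf = round(rng.uniform(0.5, 0.95), 6)
            full_conf = round(rng.uniform(0.5, 0.95), 6)
            emitted_full = full.split()[0]  # truncated prediction
        else:
            common_conf = round(rng.uniform(0.98, 1.0), 6)
            full_conf = round(rng.uniform(0.98, 1.0), 6)
            emitted_full = full
        resources.append(
            PlantedResource(
                common=common,
                full=full,
                url=urls[0],
                urls=urls,
                common_conf=common_conf,
                full_conf=full_conf,
                corrupted=corrupted,
            )
        )
        name_dict[common] = ("common", common_conf)
        name_dict[emitted_full] = ("full", full_conf)

    # article slots: one per positive (duplicated resources get two), rest negative
    resource_slots = list(range(n_resources)) + list(range(spec.dup_pairs))
    slots: list[int | None] = resource_slots + [None] * (spec.n_articles - n_pos)
    rng.shuffle(slots)

    tagger = RuleBackend(name_dict=name_dict)
    articles: list[ArticleRecord] = []
    truth_articles: dict[str, PlantedArticle] = {}
    for i, slot in enumerate(slots):
        pmid = str(6_000_000 + i)
        pub_date = f"{2015 + i % 7}-{1 + i % 12:02d}-{1 + i % 28:02d}"
        topic = _TOPICS[i % len(_TOPICS)]
        if slot is None:
            url = f"https://lab{i}.example.edu/supplement"
            title = f"A survey of {topic} across natural populations"
            abstract = (
                f"We analysed {100 + i} samples to characterise {topic}. "
                f"Supplementary material can be found at {url}. "
                "Our results suggest broad variation across conditions."
            )
            mentions: list[tuple[str, NameKind, float]] = []
            urls = [url]
        else:
            res = resources[slot]
            second_visit = pmid not in res.pmids and bool(res.pmids)
            if second_visit:  # duplicate article: later date, same facts
                pub_date = f"{2022}-{1 + i % 12:02d}-{1 + i % 28:02d}"
            title = f"{res.common}: a resource for {topic}"
            abstract = (
                f"{res.full} ({res.common}) is a database of {topic}. "
                f"The current release holds {500 + 13 * i} curated entries. "
                f"{res.common} is freely available at {res.urls[0]}."
            )
            if len(res.urls) > 1:
                abstract += f" A mirror is hosted at {res.urls[1]}."
            res.pmids.append(pmid)
            emitted_full = res.full if not res.corrupted else res.full.split()[0]
            mentions = [
                (res.common, "common", res.common_conf),
                (emitted_full, "full", res.full_conf),
            ]
            urls = list(res.urls)
        article = ArticleRecord(
            pmid=pmid, title=title, abstract=abstract, pub_date=pub_date, language="eng"
        )
        articles.append(article)
        text = prepare_text(title, abstract)
        bio_labels = [p.label for p in tagger.tag(text)]
        truth_articles[pmid] = PlantedArticle(
            pmid=pmid,
            is_positive=slot is not None,
            resource_index=slot,
            urls=urls,
            mentions=mentions,
            bio_labels=bio_labels,
        )

    return articles, GroundTruth(
        resources=resources, articles=truth_articles, name_dict=name_dict
    )


# ---------------------------------------------------------------------------
# offline service clients
# ---------------------------------------------------------------------------


class FixtureLiteratureClient:
    """Cursor-paged literature API over an in-memory article list."""

    def __init__(self, articles: Sequence[ArticleRecord]):
        self._hits = [
            {
                "id": a.pmid or f"noid{i}",
                "pmid": a.pmid,
                "title": a.title,
                "abstractText": a.abstract,
                "firstPublicationDate": a.pub_date,
                "language": a.language,
            }
            for i, a in enumerate(articles)
        ]
        self.page_requests = 0

    def search(self, query: str, cursor: str | None, page_size: int):
        self.page_requests += 1
        start = int(cursor) if cursor else 0
        page = self._hits[start : start + page_size]
        next_cursor = str(start + page_size) if start + page_size < len(self._hits) else None
        return page, next_cursor


class FixtureHttpClient:
    """Scripted HTTP checker.

    ``script`` maps a URL to either a status code or a sequence of
    per-attempt outcomes, each an int status or ``"timeout"``. URLs not
    in the script answer ``default_status``.
    """

    def __init__(self, script: Mapping[str, object] | None = None, default_status: int = 200):
        self.script = dict(script or {})
        self.default_status = default_status
        self.calls: list[tuple[str, float]] = []
        self._cursor: dict[str, int] = {}

    def get(self, url: str, timeout: float) -> int:
        self.calls.append((url, timeout))
        outcome = self.script.get(url, self.default_status)
        if isinstance(outcome, (list, tuple)):
            idx = min(self._cursor.get(url, 0), len(outcome) - 1)
            self._cursor[url] = idx + 1
            outcome = outcome[idx]
        if outcome == "timeout":
            raise TimeoutError(f"no response from {url} within {timeout}s")
        return int(outcome)


class FixtureArchiveClient:
    """Web-archive stand-in; records submissions for inspection."""

    def __init__(self, snapshots: Mapping[str, str] | None = None):
        self.snapshots = dict(snapshots or {})
        self.submissions: list[str] = []

    def latest_snapshot(self, url: str) -> str | None:
        return self.snapshots.get(url)

    def submit(self, url: str) -> str:
        self.submissions.append(url)
        snapshot = f"https://web.archive.org/web/2/{url}"
        self.snapshots[url] = snapshot
        return snapshot


class FixtureGeoProvider:
    """Maps host-name suffixes to fixed countries."""

    def __init__(
        self,
        name: str = "fixture-geo",
        suffix_map: Mapping[str, tuple[str, str, float, float]] | None = None,
    ):
        self.name = name
        self.suffix_map = dict(
            suffix_map or {".org": ("United States of America", "USA", 38.9, -77.0)}
        )
        self.queries: list[str] = []

    def locate(self, ip: str) -> GeoLocation | None:
        self.queries.append(ip)
        for suffix, (country, alpha3, lat, lon) in self.suffix_map.items():
            if ip.endswith(suffix):
                return GeoLocation(
                    source="ip", country=country, alpha3=alpha3, lat=lat, lon=lon,
                    provider=self.name,
                )
        return None


class FixtureResolver:
    """Deterministic host -> pseudo-IP resolver (keeps the host suffix)."""

    def __call__(self, host: str) -> str:
        return host  # fixture "IP" is the host itself; suffix mapping still works


class FixtureMetadataClient:
    """Deterministic article metadata derived from the ground truth."""

    _AGENCIES = [
        "National Science Agency",
        "Continental Research Council",
        "Open Data Charity",
        "Ministry of Higher Learning",
    ]
    _COUNTRIES = ["Japan", "Germany", "United Kingdom", "Brazil"]

    def __init__(self, truth: GroundTruth):
        self.truth = truth

    def metadata(self, pmid: str) -> dict | None:
        planted = self.truth.articles.get(pmid)
        if planted is None:
            return None
        idx = planted.resource_index if planted.resource_index is not None else int(pmid) % 7
        return {
            "affiliation": [
                f"Institute of Data Science, University {idx}, {self._COUNTRIES[idx % 4]}"
            ],
            "fullName": [f"Researcher {idx}"],
            "grantID": [f"G-{idx:04d}"],
            "agency": [self._AGENCIES[idx % 4]],
            "citedByCount": (idx * 7) % 50,
        }


@dataclass
class FixtureServices:
    """Offline clients for every network service the pipeline touches."""

    literature: FixtureLiteratureClient
    backend: RuleBackend
    http: FixtureHttpClient
    archive: FixtureArchiveClient
    geo_providers: list[FixtureGeoProvider]
    metadata: FixtureMetadataClient
    resolver: FixtureResolver


def fixture_services(
    truth: GroundTruth,
    articles: Sequence[ArticleRecord],
    url_script: Mapping[str, object] | None = None,
) -> FixtureServices:
    """Bundle offline stand-ins answering from the ground truth.

    ``url_script`` overrides per-URL HTTP behaviour (status int,
    ``"timeout"``, or a per-attempt sequence); planted URLs default to a
    live 200.
    """
    return FixtureServices(
        literature=FixtureLiteratureClient(articles),
        backend=RuleBackend(name_dict=truth.name_dict),
        http=FixtureHttpClient(script=url_script),
        archive=FixtureArchiveClient(),
        geo_providers=[FixtureGeoProvider()],
        metadata=FixtureMetadataClient(truth),
        resolver=FixtureResolver(),
    )
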