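"""Corpus retrieval and text preparation.

Retrieves article records from a literature API (Europe PMC style,
cursor-paged) or from injected fixture clients, and prepares
title + abstract text for classification.
"""

from __future__ import annotations

import json
import logging
import re
import time
from pathlib import Path
from typing import Callable, Iterable, Iterator, Protocol

from .exceptions import ConfigurationError, RetrievalError
from .records import ArticleRecord, Query

logger = logging.getLogger(__name__)

#: sentence punctuation that triggers space insertion at a tag-removal join
_JOIN_PUNCT = ".,;:!?"
_TAG_RE = re.compile(r"<[^<>]*?>")


class LiteratureClient(Protocol):
    """Contract for a cursor-paged literature search API.

    ``search`` returns one page of hits (as raw dicts) plus the cursor for
    the next page, or ``None`` when exhausted.
    """

    def search(
        self, query: str, cursor: str | None, page_size: int
    ) -> tuple[list[dict], str | None]: ...


def load_query(path: str | Path) -> Query:
    """Read a user-provided query file.

    Line endings are normalized to ``\\n`` and trailing whitespace is
    stripped. An empty (or whitespace-only) file is a configuration
    error, as is an obviously malformed query (unpaired quotes or
    parentheses).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"query file not found: {path}")
    text = path.read_text(encoding="utf-8")
    text = text.replace("\r\n", "\n").replace("\r", "\n").strip()
    if not text:
        raise ConfigurationError(f"query file is empty: {path}")
    _smoke_test_query(text, path)
    return Query(text=text, source_path=str(path))


def _smoke_test_query(text: str, path: Path) -> None:
    if text.count('"') % 2 != 0:
        raise ConfigurationError(f"unpaired double quote in query file {path}")
    depth = 0
    in_quote = False
    for ch in text:
        if ch == '"':
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    break
    if depth != 0:
        raise ConfigurationError(f"unpaired parenthesis in query file {path}")


def _record_from_hit(hit: dict) -> ArticleRecord:
    pmid = hit.get("pmid") or None
    return ArticleRecord(
        pmid=pmid,
        title=hit.get("title", "") or "",
        abstract=hit.get("abstractText", hit.get("abstract", "")) or "",
        pub_date=hit.get("firstPublicationDate", hit.get("pubDate", "")) or "",
        language=hit.get("language", "") or "",
        raw=hit,
    )


def fetch_articles(
    query: Query,
    client: LiteratureClient,
    page_size: int = 1000,
    max_records: int | None = None,
    retries: int = 3,
    sleep: Callable[[float], None] = time.sleep,
) -> Iterator[ArticleRecord]:
    """Stream every hit for ``query`` exactly once via cursor paging.

    Hits whose identity (pmid when present, otherwise the raw ``id``
    field) has already been seen are skipped, so a hit duplicated across
    page boundaries yields a single record. Page requests are retried up
    to ``retries`` times with exponential backoff before raising
    :class:`RetrievalError`.
    """
    seen: set[str] = set()
    cursor: str | None = None
    yielded = 0
    while True:
        hits, next_cursor = _search_with_retry(
            client, query.text, cursor, page_size, retries, sleep
        )
        for hit in hits:
            key = hit.get("pmid") or hit.get("id") or json.dumps(hit, sort_keys=True)
            if key in seen:
                continue
            seen.add(key)
            yield _record_from_hit(hit)
            yielded += 1
            if max_records is not None and yielded >= max_records:
                return
        if next_cursor is None or not hits:
            return
        cursor = next_cursor


def _search_with_retry(client, text, cursor, page_size, retries, sleep):
    last_exc: Exception | None = None
    for attempt in range(retries):
        try:
            return client.search(text, cursor, page_size)
        except Exception as exc:  # noqa: BLE001 - client errors are opaque
            last_exc = exc
            if attempt < retries - 1:
                sleep(2**attempt)
    status = getattr(last_exc, "status", None)
    raise RetrievalError(
        f"literature API failed after {retries} attempts: {last_exc}",
        last_status=status,
    )


def drop_missing_pmid(articles: Iterable[ArticleRecord]) -> list[ArticleRecord]:
    """Keep only records carrying a PMID, preserving order.

    Metadata for articles without PMIDs is generally too sparse for the
    downstream enrichment steps, so they are dropped (and counted).
    """
    kept, dropped = [], 0
    for article in articles:
        if article.pmid:
            kept.append(article)
        else:
            dropped += 1
    if dropped:
        logger.info("drop_missing_pmid: dropped %d records without a PMID", dropped)
    return kept


def prepare_text(title: str, abstract: str) -> str:
    """Build the classification input: title + single space + abstract.

    XML/HTML tags are removed; where removing a tag would glue a
    sentence-punctuation character directly onto the following word
    (``end.<p>Next`` -> ``end.Next``), a single space is inserted at the
    join. Whitespace is collapsed so the result is stable under
    re-application.
    """
    joined = " ".join(part for part in (title, abstract) if part)
    # iterate to a fixpoint: removal can expose bracket pairs that then
    # themselves read as tags (e.g. nested or split angle brackets)
    while True:
        stripped = _strip_tags(joined)
        if stripped == joined:
            break
        joined = stripped
    return re.sub(r"\s+", " ", joined).strip()


def _strip_tags(text: str) -> str:
    out: list[str] = []
    pos = 0
    for match in _TAG_RE.finditer(text):
        out.append(text[: match.start()] if pos == 0 else text[pos : match.start()])
        before = text[match.start() - 1] if match.start() > 0 else ""
        after = text[match.end()] if match.end() < len(text) else ""
        if before in _JOIN_PUNCT and after and not after.isspace():
            out.append(" ")
        pos = match.end()
    out.append(text[pos:])
    return "".join(out)


def write_corpus(articles: Iterable[ArticleRecord], path: str | Path) -> int:
    """Write articles as JSON Lines (one record per line); returns count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for article in articles:
            fh.write(
                json.dumps(
                    {
                        "pmid": article.pmid,
                        "title": article.title,
                        "abstract": article.abstract,
                        "pubDate": article.pub_date,
                        "language": article.language,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def read_corpus(path: str | Path) -> list[ArticleRecord]:
    """Read a JSON Lines corpus written by :func:`write_corpus`."""
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            blob = json.loads(line)
            records.append(
                ArticleRecord(
                    pmid=blob.get("pmid") or None,
                    title=blob.get("title", ""),
                    abstract=blob.get("abstract", ""),
                    pub_date=blob.get("pubDate", ""),
                    language=blob.get("language", ""),
                    raw=blob,
                )
            )
    return records


class EuropePMCClient:
    """Thin cursor-paged client for the Europe PMC REST search endpoint.

    Network access is optional everywhere in the package; any object
    satisfying :class:`LiteratureClient` (e.g. the offline fixture
    client) can stand in for this one.
    """

    BASE_URL = "https://www.ebi.ac.uk/europepmc/webservices/rest/search"

    def __init__(self, base_url: str | None = None, timeout: float = 30.0):
        self.base_url = base_url or self.BASE_URL
        self.timeout = timeout

    def search(self, query: str, cursor: str | None, page_size: int):
        import urllib.parse
        import urllib.request

        params = {
            "query": query,
            "format": "json",
            "resultType": "core",
            "pageSize": str(page_size),
            "cursorMark": cursor or "*",
        }
        url = f"{self.base_url}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            payload = json.load(resp)
        hits = payload.get("resultList", {}).get("result", [])
        next_cursor = payload.get("nextCursorMark")
        if next_cursor == cursor:
            next_cursor = None
        return hits, next_cursor
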