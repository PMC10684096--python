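"""Post-review enrichment: article metadata, URL viability, geolocation.

URL viability follows a fixed protocol: up to three attempts with a
5-second response window each, the second attempt immediately after the
first and the third after a one-second delay; a site is alive iff some
attempt returned an HTTP status in the 2xx or 3xx series. Geolocation
comes from two directions — the URL host's IP address (infrastructure
location) and ISO-3166 country mentions in author affiliations
(contributor locations). Every network operation takes an injected
client so the whole module runs offline against fixtures.
"""

from __future__ import annotations

import csv
import logging
import re
import time
from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources as importlib_resources
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import pandas as pd

from .exceptions import EnrichmentError
from .records import ArticleMetadata, GeoLocation, ResourceRecord, UrlStatus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# client contracts
# ---------------------------------------------------------------------------


class MetadataClient(Protocol):
    """Returns raw metadata for one PMID, or None when unknown."""

    def metadata(self, pmid: str) -> dict | None: ...


class HttpClient(Protocol):
    """Issues one GET without following redirects; returns the status code.

    Raises ``TimeoutError`` / ``ConnectionError`` on failure to obtain
    any status.
    """

    def get(self, url: str, timeout: float) -> int: ...


class ArchiveClient(Protocol):
    """Web-archive availability contract."""

    def latest_snapshot(self, url: str) -> str | None: ...

    def submit(self, url: str) -> str | None: ...


class GeoProvider(Protocol):
    name: str

    def locate(self, ip: str) -> GeoLocation | None: ...


# ---------------------------------------------------------------------------
# metadata augmentation
# ---------------------------------------------------------------------------


def augment_metadata(
    pmids: Sequence[str],
    client: MetadataClient,
    retries: int = 3,
    sleep: Callable[[float], None] = time.sleep,
) -> dict[str, ArticleMetadata]:
    """Fetch affiliation/author/grant/citation metadata per PMID.

    A PMID the client does not know yields an all-absent entry with a
    warning, not an error; a client that keeps failing raises
    :class:`EnrichmentError`.
    """
    if not pmids:
        raise ValueError("pmids must be non-empty")
    out: dict[str, ArticleMetadata] = {}
    for pmid in pmids:
        blob = _fetch_with_retry(client, pmid, retries, sleep)
        if blob is None:
            logger.warning("no metadata for pmid %s", pmid)
            out[pmid] = ArticleMetadata(pmid=pmid)
            continue
        out[pmid] = ArticleMetadata(
            pmid=pmid,
            affiliations=list(blob.get("affiliation", []) or []),
            authors=list(blob.get("fullName", []) or []),
            grant_ids=list(blob.get("grantID", []) or []),
            agencies=list(blob.get("agency", []) or []),
            cited_by=int(blob.get("citedByCount", 0) or 0),
        )
    return out


def _fetch_with_retry(client, pmid, retries, sleep):
    last_exc = None
    for attempt in range(retries):
        try:
            return client.metadata(pmid)
        except Exception as exc:  # noqa: BLE001
            last_exc = exc
            if attempt < retries - 1:
                sleep(2**attempt)
    raise EnrichmentError(f"metadata client failed for pmid {pmid}: {last_exc}")


# ---------------------------------------------------------------------------
# URL viability
# ---------------------------------------------------------------------------


def check_url(
    url: str,
    client: HttpClient,
    timeout: float = 5.0,
    sleep: Callable[[float], None] = time.sleep,
) -> UrlStatus:
    """Probe a URL with the three-attempt viability protocol.

    Attempt 2 follows attempt 1 immediately; attempt 3 follows a
    one-second delay. The first definitive HTTP status ends the probe;
    failures to obtain any status (timeouts, connection errors) are data,
    not exceptions. Alive iff the status is in 2xx/3xx.
    """
    status: int | None = None
    attempts = 0
    for attempt in range(1, 4):
        if attempt == 3:
            sleep(1.0)
        attempts = attempt
        try:
            status = client.get(url, timeout=timeout)
        except (TimeoutError, ConnectionError, OSError):
            status = None
            continue
        break
    alive = status is not None and 200 <= status < 400
    return UrlStatus(
        url=url,
        attempts=attempts,
        status_code=status,
        alive=alive,
        checked_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def wayback_lookup(
    url: str, archive: ArchiveClient, alive: bool = False
) -> str | None:
    """Return the most recent archived snapshot URL, if any.

    A live URL with no snapshot is submitted for archiving once and the
    resulting snapshot URL recorded; a dead, unarchived URL stays
    absent. Archive-client failures degrade to absent with a warning.
    """
    try:
        snapshot = archive.latest_snapshot(url)
        if snapshot:
            return snapshot
        if alive:
            return archive.submit(url)
        return None
    except Exception as exc:  # noqa: BLE001
        logger.warning("archive lookup failed for %s: %s", url, exc)
        return None


# ---------------------------------------------------------------------------
# geolocation
# ---------------------------------------------------------------------------


def geolocate_ip(
    url_status: UrlStatus,
    providers: Sequence[GeoProvider],
    resolver: Callable[[str], str] | None = None,
) -> GeoLocation | None:
    """Geolocate the host IP of a URL that responded with status < 400.

    Providers are queried in the configured order; the first success
    supplies country and coordinates. Resolution failure yields None.
    Calling this for a status >= 400 (or no status) violates the
    protocol gate and raises ``ValueError``.
    """
    if url_status.status_code is None or url_status.status_code >= 400:
        raise ValueError("geolocate_ip requires an HTTP status < 400")
    host = re.sub(r"^[a-z+]+://", "", url_status.url, flags=re.IGNORECASE)
    host = host.split("/")[0].split(":")[0]
    if resolver is None:
        import socket

        resolver = socket.gethostbyname
    try:
        ip = resolver(host)
    except OSError:
        return None
    for provider in providers:
        try:
            location = provider.locate(ip)
        except Exception:  # noqa: BLE001 - provider outage: fall through
            continue
        if location is not None:
            return location
    return None


@dataclass(frozen=True)
class CountryEntry:
    name: str
    alpha2: str
    alpha3: str


def load_iso3166() -> list[CountryEntry]:
    """Load the bundled ISO-3166-1 table (name, alpha2, alpha3)."""
    ref = importlib_resources.files("biodata_inventory").joinpath("data/iso3166.csv")
    with ref.open(encoding="utf-8") as fh:
        return [
            CountryEntry(row["name"], row["alpha2"], row["alpha3"])
            for row in csv.DictReader(fh)
        ]


_ALPHA3_TOKEN_RE = re.compile(r"\b[A-Z]{3}\b")


def match_countries(
    text: str,
    table: Sequence[CountryEntry] | None = None,
    word_boundary: bool = False,
) -> list[tuple[str, str]]:
    """Find ISO-3166-1 countries mentioned in free text.

    Country names match as case-insensitive substrings (the default
    mirrors how affiliation mining behaves in practice, including its
    known artifacts: "New Mexico" matches Mexico, while "South Korea"
    misses "Republic of Korea"). Alpha-3 codes match only as standalone
    uppercase tokens, since substring matching of three-letter codes is
    pathologically noisy. Each country is reported once, in table order.
    ``word_boundary=True`` switches names to whole-word matching.
    """
    if table is None:
        table = load_iso3166()
    lowered = text.lower()
    codes = set(_ALPHA3_TOKEN_RE.findall(text))
    hits: list[tuple[str, str]] = []
    for entry in table:
        name_hit = (
            re.search(rf"\b{re.escape(entry.name.lower())}\b", lowered) is not None
            if word_boundary
            else entry.name.lower() in lowered
        )
        if name_hit or entry.alpha3 in codes:
            hits.append((entry.name, entry.alpha3))
    return hits


# ---------------------------------------------------------------------------
# funder frequency
# ---------------------------------------------------------------------------


def funder_frequency(
    resources: Sequence[ResourceRecord],
    metadata: Mapping[str, ArticleMetadata],
    min_count: int = 3,
) -> pd.DataFrame:
    """Count distinct resources per verbatim funding-agency string.

    An agency naming the same resource through several of its articles
    (or twice in one article) counts once for that resource. Agency
    strings are deliberately not normalized. Rows with fewer than
    ``min_count`` resources are dropped; the result is sorted by count
    (desc) then agency name.
    """
    counts: Counter = Counter()
    for resource in resources:
        agencies: set[str] = set()
        for pmid in resource.member_pmids:
            meta = metadata.get(pmid)
            if meta is not None:
                agencies.update(meta.agencies)
        counts.update(agencies)
    rows = [
        {"agency": agency, "n_resources": n}
        for agency, n in counts.items()
        if n >= min_count
    ]
    return (
        pd.DataFrame(rows, columns=["agency", "n_resources"])
        .sort_values(["n_resources", "agency"], ascending=[False, True])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# enriched inventory assembly
# ---------------------------------------------------------------------------


def enrich_inventory(
    resources: Sequence[ResourceRecord],
    metadata_client: MetadataClient,
    http_client: HttpClient,
    archive: ArchiveClient,
    providers: Sequence[GeoProvider],
    resolver: Callable[[str], str] | None = None,
    sleep: Callable[[float], None] = time.sleep,
    iso_table: Sequence[CountryEntry] | None = None,
) -> pd.DataFrame:
    """Produce the enriched inventory table.

    Adds, per resource: HTTP status and liveness of its URL, the most
    recent archive snapshot, IP-derived country/coordinates, affiliation
    countries (alpha-3, ;-separated), verbatim agency names, and total
    citations across member articles.
    """
    if iso_table is None:
        iso_table = load_iso3166()
    all_pmids = sorted({p for r in resources for p in r.member_pmids})
    metadata = (
        augment_metadata(all_pmids, metadata_client, sleep=sleep) if all_pmids else {}
    )
    rows = []
    for r in resources:
        status = check_url(r.url, http_client, sleep=sleep)
        wayback = wayback_lookup(r.url, archive, alive=status.alive)
        geo = None
        if status.status_code is not None and status.status_code < 400:
            geo = geolocate_ip(status, providers, resolver=resolver)
        metas = [metadata[p] for p in r.member_pmids if p in metadata]
        affil_text = " ; ".join(a for m in metas for a in m.affiliations)
        affil_countries = match_countries(affil_text, table=iso_table) if affil_text else []
        agencies = sorted({a for m in metas for a in m.agencies})
        rows.append(
            {
                "resource_id": r.resource_id,
                "best_name": r.best_name,
                "url": r.url,
                "http_status": status.status_code,
                "url_alive": status.alive,
                "wayback_url": wayback or "",
                "ip_country": geo.country if geo else "",
                "ip_lat": geo.lat if geo else None,
                "ip_lon": geo.lon if geo else None,
                "affiliation_countries": ";".join(a3 for _, a3 in affil_countries),
                "agencies": ";".join(agencies),
                "cited_by_total": sum(m.cited_by for m in metas),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ArchiveClient",
    "CountryEntry",
    "GeoProvider",
    "HttpClient",
    "MetadataClient",
    "augment_metadata",
    "check_url",
    "enrich_inventory",
    "funder_frequency",
    "geolocate_ip",
    "load_iso3166",
    "match_countries",
    "wayback_lookup",
]
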