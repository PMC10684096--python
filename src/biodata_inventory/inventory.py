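"""Candidate filtering, deduplication, review flagging, and the pipeline.

Per-article predictions become inventory candidates only when positively
classified with at least one decoded name, a long-enough best name, and
1..max_urls complete URLs. Candidates that agree on (exact best name,
normalized URL) merge into one resource record; records are then flagged
for manual review (low-confidence best name, shared names, shared URLs)
and a curator's review file is validated and applied to finalize the
inventory. Predicted names and URLs are never edited — the review can
only keep, remove, or merge records — so every value in the final
inventory remains machine-generated.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import urlsplit

from .exceptions import NormalizationError, ValidationError
from .records import (
    FLAG_DUP_NAMES,
    FLAG_DUP_URLS,
    FLAG_LOW_PROB,
    ArticlePrediction,
    CandidateRecord,
    ResourceRecord,
    ReviewDecision,
    resource_id_for,
)

logger = logging.getLogger(__name__)

#: closed vocabulary of review actions (merge-like actions carry a target id)
REVIEW_ACTIONS = ("keep", "remove", "merge", "partial_merge")


@dataclass(frozen=True)
class InventoryConfig:
    """Thresholds governing filtering and review flagging.

    ``review_threshold`` is the best-name probability below which (strictly)
    a record is flagged low_prob: the mean probability of names judged
    correct in a manual evaluation of a 10% sample of predictions.
    ``max_urls`` drops multi-resource abstracts (>2 URLs nearly always
    describe several distinct resources); ``min_name_length`` drops
    single-character names.
    """

    review_threshold: float = 0.978
    max_urls: int = 2
    min_name_length: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.review_threshold < 1.0:
            raise ValueError("review_threshold must be in (0, 1)")


def normalize_url(url: str) -> str:
    """Reduce a URL to its comparison key.

    Scheme differences (http vs https) and trailing slashes are ignored;
    the key is lowercased. The original URL is kept separately for
    display. Strings without a host component are not complete URLs and
    raise :class:`NormalizationError`.
    """
    if not isinstance(url, str) or not url.strip():
        raise NormalizationError(f"not a URL: {url!r}")
    candidate = url.strip()
    if "://" not in candidate:
        candidate = "http://" + candidate
    parts = urlsplit(candidate)
    if not parts.netloc or "." not in parts.netloc:
        raise NormalizationError(f"URL has no host component: {url!r}")
    key = parts.netloc + parts.path
    if parts.query:
        key += "?" + parts.query
    return key.rstrip("/").lower()


def is_complete_url(url: str) -> bool:
    """A URL is complete when it normalizes and has a host."""
    try:
        normalize_url(url)
        return True
    except NormalizationError:
        return False


def apply_prediction_filters(
    predictions: Iterable[ArticlePrediction],
    config: InventoryConfig = InventoryConfig(),
) -> tuple[list[CandidateRecord], Counter]:
    """Filter predictions down to inventory candidates.

    Keeps records that are positively classified AND have >= 1 decoded
    name AND a best name of at least ``min_name_length`` characters AND
    between 1 and ``max_urls`` complete URLs. Returns the candidates and
    a per-rule Counter of dropped records (rules: ``classification``,
    ``no_name``, ``name_length``, ``no_url``, ``url_count``).
    """
    candidates: list[CandidateRecord] = []
    drops: Counter = Counter()
    for pred in predictions:
        if not pred.classification.is_positive:
            drops["classification"] += 1
            continue
        best = pred.best_names
        if best.best_name is None:
            drops["no_name"] += 1
            continue
        if len(best.best_name.text) < config.min_name_length:
            drops["name_length"] += 1
            continue
        urls = [u for u in pred.urls if is_complete_url(u)]
        if not urls:
            drops["no_url"] += 1
            continue
        if len(urls) > config.max_urls:
            drops["url_count"] += 1
            continue
        candidates.append(
            CandidateRecord(
                pmid=pred.pmid,
                best_names=best,
                urls=urls,
                best_prob=best.best_name.confidence,
                title_abstract=pred.title_abstract,
                pub_date=pred.pub_date,
            )
        )
    if drops:
        logger.info("apply_prediction_filters drops: %s", dict(drops))
    return candidates, drops


def deduplicate(candidates: Sequence[CandidateRecord]) -> list[ResourceRecord]:
    """Merge candidates sharing (exact best name, normalized URL).

    Name comparison is case-sensitive ("Seed" and "SEED" are different
    resources); URL comparison uses the normalized key. A merged record
    keeps the union of member PMIDs plus the title-abstract text and
    publication date of the most recently published article (first
    encountered on a date tie). Output order follows first appearance of
    each (name, URL) group, so the operation is idempotent and
    order-invariant up to resource ordering.
    """
    groups: dict[tuple[str, str], ResourceRecord] = {}
    for cand in candidates:
        if isinstance(cand, ResourceRecord):  # re-dedup of an existing inventory
            name, url = cand.best_name, cand.url
            common = cand.best_common
            full = cand.best_full
            pmids = list(cand.member_pmids)
            text, date = cand.latest_title_abstract, cand.latest_date
            all_urls = list(cand.urls) or [url]
        else:
            name, url = cand.best_names.best_name.text, cand.urls[0]
            common = cand.best_names.best_common.text if cand.best_names.best_common else None
            full = cand.best_names.best_full.text if cand.best_names.best_full else None
            pmids = [cand.pmid] if cand.pmid else []
            text, date = cand.title_abstract, cand.pub_date
            all_urls = list(cand.urls)
        url_key = normalize_url(url)
        key = (name, url_key)
        existing = groups.get(key)
        if existing is None:
            groups[key] = ResourceRecord(
                resource_id=resource_id_for(name, url_key),
                best_name=name,
                best_common=common,
                best_full=full,
                url=url,
                url_key=url_key,
                member_pmids=list(pmids),
                best_prob=cand.best_prob,
                latest_title_abstract=text,
                latest_date=date,
                urls=all_urls,
            )
            continue
        for pmid in pmids:
            if pmid not in existing.member_pmids:
                existing.member_pmids.append(pmid)
        for u in all_urls:
            if u not in existing.urls:
                existing.urls.append(u)
        existing.best_prob = max(existing.best_prob, cand.best_prob)
        if date > existing.latest_date:
            existing.latest_title_abstract = text
            existing.latest_date = date
    return list(groups.values())


def flag_for_review(
    resources: Sequence[ResourceRecord],
    config: InventoryConfig = InventoryConfig(),
) -> list[ResourceRecord]:
    """Attach review flags; flags are computed, never hand-set.

    ``low_prob`` iff best_prob < threshold (strict: exactly 0.978 is not
    flagged); ``duplicate_names`` iff >= 2 records share a best name;
    ``duplicate_urls`` iff >= 2 records share a normalized URL. Flags are
    additive.
    """
    name_counts = Counter(r.best_name for r in resources)
    url_counts = Counter(r.url_key for r in resources)
    for record in resources:
        record.flags = set()
        if record.best_prob < config.review_threshold:
            record.flags.add(FLAG_LOW_PROB)
        if name_counts[record.best_name] >= 2:
            record.flags.add(FLAG_DUP_NAMES)
        if url_counts[record.url_key] >= 2:
            record.flags.add(FLAG_DUP_URLS)
    return list(resources)


def _parse_action(action: str) -> tuple[str, str | None]:
    verb, _, target = action.partition(":")
    return verb, (target or None)


def validate_review(
    resources: Sequence[ResourceRecord], decisions: Sequence[ReviewDecision]
) -> None:
    """Strictly validate a review file against the flagged inventory.

    Errors name the offending row: unknown action verbs, merge actions
    without a known target, decisions for unknown records, and flagged
    records left without a decision are all validation errors.
    """
    ids = {r.resource_id for r in resources}
    decided = set()
    for row, decision in enumerate(decisions, start=1):
        verb, target = _parse_action(decision.action)
        if verb not in REVIEW_ACTIONS:
            raise ValidationError(
                f"row {row}: unknown review action {decision.action!r}"
            )
        if verb in ("merge", "partial_merge"):
            if target is None:
                raise ValidationError(f"row {row}: {verb} requires a target id")
            if target not in ids:
                raise ValidationError(f"row {row}: merge target {target!r} not in inventory")
        if decision.resource_id not in ids:
            raise ValidationError(
                f"row {row}: decision for unknown record {decision.resource_id!r}"
            )
        decided.add(decision.resource_id)
    missing = [r.resource_id for r in resources if r.flags and r.resource_id not in decided]
    if missing:
        raise ValidationError(
            f"flagged records without a review decision: {', '.join(sorted(missing))}"
        )


def validate_and_apply_review(
    resources: Sequence[ResourceRecord], decisions: Sequence[ReviewDecision]
) -> list[ResourceRecord]:
    """Apply curator decisions to produce the final inventory.

    ``remove`` drops the record; ``merge:<target>`` moves the record's
    member PMIDs into the target record and drops it; ``partial_merge``
    behaves the same for the decided record (its partial character lies
    in being issued for only part of a duplicate set); ``keep`` retains
    the record unchanged. ML-predicted names and URLs are never edited.
    """
    validate_review(resources, decisions)
    by_id = {r.resource_id: r for r in resources}
    removed: set[str] = set()
    for decision in decisions:
        verb, target = _parse_action(decision.action)
        if verb == "keep":
            continue
        if verb == "remove":
            removed.add(decision.resource_id)
            continue
        # merge / partial_merge
        source = by_id[decision.resource_id]
        sink = by_id[target]
        for pmid in source.member_pmids:
            if pmid not in sink.member_pmids:
                sink.member_pmids.append(pmid)
        removed.add(decision.resource_id)
    return [r for r in resources if r.resource_id not in removed]


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class StageReport:
    """Ordered per-stage record counts for a pipeline run."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, count: int) -> None:
        self.stages.append((name, count))

    def counts(self) -> list[int]:
        return [c for _, c in self.stages]

    def __str__(self) -> str:
        return "\n".join(f"{name}: {count}" for name, count in self.stages)


def predict_articles(articles, backend) -> list[ArticlePrediction]:
    """Run classification, tagging, and URL extraction over a corpus."""
    from .corpus import prepare_text
    from .extraction import classify_article, decode_mentions, extract_urls

    predictions = []
    for article in articles:
        text = prepare_text(article.title, article.abstract)
        if not text:
            continue
        result = classify_article(text, backend)
        mentions = decode_mentions(backend.tag(text)) if result.is_positive else []
        predictions.append(
            ArticlePrediction(
                pmid=article.pmid,
                classification=result,
                mentions=mentions,
                urls=extract_urls(article.abstract),
                title_abstract=text,
                pub_date=article.pub_date,
            )
        )
    return predictions


def run_pipeline(
    articles,
    backend,
    config: InventoryConfig = InventoryConfig(),
) -> tuple[list[ResourceRecord], StageReport]:
    """Execute retrieve -> classify -> tag -> filter -> dedup -> flag.

    Returns the flagged preliminary inventory plus the stage-count
    report (counts are monotonically non-increasing from classification
    onward). The run pauses here for manual review;
    :func:`validate_and_apply_review` resumes it.
    """
    from .corpus import drop_missing_pmid

    report = StageReport()
    articles = list(articles)
    report.add("retrieved", len(articles))
    articles = drop_missing_pmid(articles)
    report.add("with_pmid", len(articles))

    predictions = predict_articles(articles, backend)
    positives = [p for p in predictions if p.classification.is_positive]
    report.add("classified_positive", len(positives))
    named = [p for p in positives if p.mentions]
    report.add("with_name", len(named))

    candidates, _ = apply_prediction_filters(predictions, config)
    report.add("with_url", len(candidates))

    resources = deduplicate(candidates)
    report.add("after_dedup", len(resources))
    resources = flag_for_review(resources, config)
    return resources, report


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_COLUMNS = [
    "resource_id",
    "best_name",
    "best_common",
    "best_full",
    "url",
    "url_key",
    "pmids",
    "best_prob",
    "flags",
    "latest_date",
]


def write_inventory(resources: Sequence[ResourceRecord], path: str | Path) -> Path:
    """Write an inventory CSV with the documented column order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in resources:
            writer.writerow(
                [
                    r.resource_id,
                    r.best_name,
                    r.best_common or "",
                    r.best_full or "",
                    r.url,
                    r.url_key,
                    ";".join(r.member_pmids),
                    f"{r.best_prob:.6f}",
                    ";".join(sorted(r.flags)),
                    r.latest_date,
                ]
            )
    return path


def read_inventory(path: str | Path) -> list[ResourceRecord]:
    """Read an inventory CSV written by :func:`write_inventory`."""
    resources = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            resources.append(
                ResourceRecord(
                    resource_id=row["resource_id"],
                    best_name=row["best_name"],
                    best_common=row["best_common"] or None,
                    best_full=row["best_full"] or None,
                    url=row["url"],
                    url_key=row["url_key"],
                    member_pmids=[p for p in row["pmids"].split(";") if p],
                    best_prob=float(row["best_prob"]),
                    flags={f for f in row["flags"].split(";") if f},
                    latest_date=row["latest_date"],
                )
            )
    return resources


def read_review(path: str | Path) -> list[ReviewDecision]:
    """Read a review CSV (columns: resource_id, action)."""
    decisions = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"resource_id", "action"} <= set(reader.fieldnames):
            raise ValidationError("review file must have columns resource_id, action")
        for row in reader:
            decisions.append(ReviewDecision(row["resource_id"].strip(), row["action"].strip()))
    return decisions
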