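"""Comparison of the inventory against external registry exports.

Matching runs independently on three channels — common-name key,
full-name key, and cleaned URL key — then merges the matched pairs,
collapsing a pair that matched on both name and URL into one. Name keys
are only whitespace-trimmed (case-preserving, since distinctly cased
names like Seed/SEED denote distinct resources); URL keys drop the
scheme and trailing slashes and are lowercased.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .records import RegistryRecord, ResourceRecord

_SCHEME_RE = re.compile(r"^[a-z][a-z0-9+.-]*://", re.IGNORECASE)


def clean_name(name: str) -> str:
    """Name comparison key: strip surrounding whitespace only."""
    return name.strip()


def clean_url(url: str) -> str:
    """URL comparison key: drop scheme and trailing slashes, lowercase."""
    return _SCHEME_RE.sub("", url.strip()).rstrip("/").lower()


def filter_re3data(
    records: Iterable[RegistryRecord],
    subject: str = "life sciences",
    exclude: Sequence[str] = ("institutional", "other"),
) -> list[RegistryRecord]:
    """Subset a re3data export to dedicated life-sciences repositories.

    Keeps records tagged with the life-sciences subject that have a URL
    and carry none of the generalist tags (institutional/other).
    """
    excluded = {e.lower() for e in exclude}
    kept = []
    for rec in records:
        tags = {t.lower() for t in rec.subjects}
        if subject.lower() not in tags:
            continue
        if not rec.url:
            continue
        if tags & excluded:
            continue
        kept.append(rec)
    return kept


@dataclass(frozen=True)
class MatchedPair:
    inventory_id: str
    registry_source: str
    registry_name: str
    channels: tuple[str, ...]


@dataclass
class OverlapResult:
    pairs: list[MatchedPair] = field(default_factory=list)
    matched_inventory_count: int = 0


def overlap(
    inventory: Sequence[ResourceRecord], registry: Sequence[RegistryRecord]
) -> OverlapResult:
    """Count inventory resources found in a registry.

    Match sets are computed independently on the common-name, full-name,
    and URL channels; the union is reported per (inventory record,
    registry record) pair with the channels that fired, so a pair
    matching on both name and URL appears once. The headline count is
    the number of distinct inventory resources matched.
    """
    by_name: dict[str, list[RegistryRecord]] = {}
    by_url: dict[str, list[RegistryRecord]] = {}
    for rec in registry:
        if rec.name:
            by_name.setdefault(clean_name(rec.name), []).append(rec)
        if rec.url:
            by_url.setdefault(clean_url(rec.url), []).append(rec)

    pair_channels: dict[tuple[str, int], list[str]] = {}
    reg_index = {id(rec): i for i, rec in enumerate(registry)}

    def note(inv: ResourceRecord, rec: RegistryRecord, channel: str) -> None:
        key = (inv.resource_id, reg_index[id(rec)])
        chans = pair_channels.setdefault(key, [])
        if channel not in chans:
            chans.append(channel)

    for inv in inventory:
        for channel, value in (
            ("common_name", inv.best_common),
            ("full_name", inv.best_full),
        ):
            if value:
                for rec in by_name.get(clean_name(value), []):
                    note(inv, rec, channel)
        for url in inv.urls or [inv.url]:
            for rec in by_url.get(clean_url(url), []):
                note(inv, rec, "url")

    pairs = [
        MatchedPair(
            inventory_id=inv_id,
            registry_source=registry[reg_i].source,
            registry_name=registry[reg_i].name,
            channels=tuple(chans),
        )
        for (inv_id, reg_i), chans in sorted(pair_channels.items())
    ]
    matched = len({p.inventory_id for p in pairs})
    return OverlapResult(pairs=pairs, matched_inventory_count=matched)


# ---------------------------------------------------------------------------
# registry export IO
# ---------------------------------------------------------------------------


def read_registry_export(path: str | Path, source: str | None = None) -> list[RegistryRecord]:
    """Read a registry export from CSV or JSON.

    CSV columns: source, name, url, subjects (;-separated). JSON: a list
    of objects with the same fields.
    """
    path = Path(path)
    default_source = source or path.stem
    records: list[RegistryRecord] = []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    for row in rows:
        subjects = row.get("subjects", "")
        if isinstance(subjects, str):
            subjects = tuple(s.strip() for s in subjects.split(";") if s.strip())
        else:
            subjects = tuple(subjects)
        records.append(
            RegistryRecord(
                source=row.get("source") or default_source,
                name=(row.get("name") or "").strip(),
                url=(row.get("url") or "").strip(),
                subjects=subjects,
            )
        )
    return records


def write_overlap(result: OverlapResult, path: str | Path) -> Path:
    """Write the overlap report CSV (inventory_id, source, name, channels)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["inventory_id", "registry_source", "registry_name", "match_channels"])
        for pair in result.pairs:
            writer.writerow(
                [pair.inventory_id, pair.registry_source, pair.registry_name, ";".join(pair.channels)]
            )
    return path
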