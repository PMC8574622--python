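"""Combining normalized assertions into consensus ortholog calls.

Assertions from different resources that resolve to the same composite-key
pair are merged into one *combined ortholog* carrying the set of supporting
sources.  The support count — how many resources back a pair — is the
tool's proxy for reliability; no weighted confidence score is computed, by
design.  Storage is human-centric: every pair is canonicalized so the human
gene sits on the query side.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ingest import NormalizedAssertion, SourceConfig
from .registry import HUMAN_TAXON, CompositeGeneKey, EquivalencyTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombinedOrtholog:
    """A key pair plus the set of resources supporting it."""

    query_key: CompositeGeneKey
    target_key: CompositeGeneKey
    query_taxon: int
    target_taxon: int
    supporting_sources: frozenset[str]
    #: per-source pipe-joined raw assertion ID strings
    raw_assertion_ids: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.supporting_sources:
            raise ValueError("combined ortholog must have at least one supporting source")

    def support_count(self) -> int:
        return len(self.supporting_sources)

    def raw_ids_for(self, source: str) -> str:
        return dict(self.raw_assertion_ids).get(source, "")

    def all_raw_ids(self) -> str:
        """Pipe-joined raw assertion IDs across sources, source-sorted."""
        parts = [ids for _, ids in sorted(self.raw_assertion_ids) if ids]
        return "|".join(parts)


def support_count(entry: CombinedOrtholog) -> int:
    """Number of resources supporting the pair."""
    return entry.support_count()


class OrthologTable:
    """All combined orthologs from one build, indexed by human-side key."""

    def __init__(self, entries: Iterable[CombinedOrtholog] = (),
                 metadata: Optional[dict[str, str]] = None):
        self.entries: list[CombinedOrtholog] = []
        self.metadata: dict[str, str] = dict(metadata or {})
        self._by_query: dict[CompositeGeneKey, list[CombinedOrtholog]] = {}
        self._by_target: dict[CompositeGeneKey, list[CombinedOrtholog]] = {}
        self._seen: set[tuple] = set()
        for e in entries:
            self.add(e)

    def add(self, entry: CombinedOrtholog) -> None:
        k = (entry.query_key, entry.target_key, entry.query_taxon, entry.target_taxon)
        if k in self._seen:
            raise ValueError(f"duplicate combined ortholog {entry.query_key}/{entry.target_key}")
        self._seen.add(k)
        self.entries.append(entry)
        self._by_query.setdefault(entry.query_key, []).append(entry)
        self._by_target.setdefault(entry.target_key, []).append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entries_for_query(self, key: CompositeGeneKey) -> list[CombinedOrtholog]:
        return list(self._by_query.get(key, []))

    def entries_for_target(self, key: CompositeGeneKey) -> list[CombinedOrtholog]:
        return list(self._by_target.get(key, []))

    def target_taxa(self) -> set[int]:
        return {e.target_taxon for e in self.entries}


def combine(
    assertions: Sequence[NormalizedAssertion],
    sources: Optional[Sequence[SourceConfig]] = None,
    metadata: Optional[dict[str, str]] = None,
) -> OrthologTable:
    """Merge assertions sharing one canonicalized key pair into single entries.

    Direction is canonicalized human-side-first; an assertion asserted in
    either direction by a source counts once toward that source's support.
    Assertions where neither endpoint is human are rejected with a logged
    reason (the aggregation is human-centric).  When ``sources`` is given,
    each assertion's source must be configured to cover both endpoint taxa.
    """
    coverage = {s.name: s.species_covered for s in sources} if sources is not None else None

    grouped: dict[tuple, dict[str, set[str]]] = {}
    order: list[tuple] = []
    for a in assertions:
        if a.query_taxon == HUMAN_TAXON:
            pair = (a.query_key, a.target_key, a.target_taxon)
        elif a.target_taxon == HUMAN_TAXON:
            pair = (a.target_key, a.query_key, a.query_taxon)
        else:
            logger.warning(
                "rejected assertion %s:%s (taxa %d/%d): neither endpoint is human",
                a.source, a.raw_assertion_id, a.query_taxon, a.target_taxon,
            )
            continue
        if coverage is not None:
            covered = coverage.get(a.source)
            if covered is None:
                raise ValueError(f"assertion from unconfigured source {a.source!r}")
            if not {HUMAN_TAXON, pair[2]} <= covered:
                raise ValueError(
                    f"source {a.source!r} not configured for taxa 9606/{pair[2]}"
                )
        if pair not in grouped:
            order.append(pair)
            grouped[pair] = {}
        ids = {i for i in a.raw_assertion_id.split("|") if i}
        grouped[pair].setdefault(a.source, set()).update(ids)

    table = OrthologTable(metadata=metadata)
    for pair in sorted(order, key=lambda p: (p[2], p[0].display(), p[1].display())):
        human_key, other_key, other_taxon = pair
        per_source = grouped[pair]
        table.add(CombinedOrtholog(
            query_key=human_key,
            target_key=other_key,
            query_taxon=HUMAN_TAXON,
            target_taxon=other_taxon,
            supporting_sources=frozenset(per_source),
            raw_assertion_ids=tuple(
                (src, "|".join(sorted(ids))) for src, ids in sorted(per_source.items())
            ),
        ))
    return table


def results_for(
    table: OrthologTable,
    gene_key: CompositeGeneKey,
    target_taxa: set[int],
    included_sources: set[str],
    registries: Optional[dict[int, EquivalencyTable]] = None,
) -> list[CombinedOrtholog]:
    """Ortholog entries for one human-side gene, ordered by support.

    Entries supported *only* by excluded sources are dropped; an entry with
    mixed support survives and keeps its full supporting set, so excluded
    sources still show as supporters of retained entries.  Within each
    target taxon the entry backed by the most resources comes first; ties
    break on ascending target symbol (when registries are supplied), then
    on the target key's display string.
    """
    hits = [
        e for e in table.entries_for_query(gene_key)
        if e.target_taxon in target_taxa
        and e.supporting_sources & included_sources
    ]

    def sort_key(e: CombinedOrtholog):
        symbol = ""
        if registries is not None and e.target_taxon in registries:
            rec = registries[e.target_taxon].lookup_key(e.target_key)
            if rec is not None:
                symbol = rec.symbol
        return (e.target_taxon, -e.support_count(), symbol, e.target_key.display())

    return sorted(hits, key=sort_key)


# ---------------------------------------------------------------------------
# diffable TSV snapshot

SNAPSHOT_COLUMNS = (
    "query_taxon", "query_key", "target_taxon", "target_key",
    "sources", "raw_assertion_ids",
)


def write_snapshot(table: OrthologTable, path: str | Path) -> int:
    """Persist the table as a sorted TSV snapshot (byte-stable across runs)."""
    path = Path(path)
    rows = sorted(
        table.entries,
        key=lambda e: (e.target_taxon, e.query_key.display(), e.target_key.display()),
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SNAPSHOT_COLUMNS)
        for e in rows:
            writer.writerow([
                e.query_taxon, e.query_key.display(),
                e.target_taxon, e.target_key.display(),
                "|".join(sorted(e.supporting_sources)),
                # ";" between sources because raw IDs are pipe-joined within one
                ";".join(f"{src}:{ids}" for src, ids in sorted(e.raw_assertion_ids)),
            ])
    return len(rows)


def read_snapshot(path: str | Path, metadata: Optional[dict[str, str]] = None) -> OrthologTable:
    path = Path(path)
    entries = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != list(SNAPSHOT_COLUMNS):
            raise ValueError(f"{path}: bad snapshot header {reader.fieldnames}")
        for row in reader:
            raw_ids = []
            for part in (row["raw_assertion_ids"] or "").split(";"):
                if ":" in part:
                    src, ids = part.split(":", 1)
                    raw_ids.append((src, ids))
            entries.append(CombinedOrtholog(
                query_key=CompositeGeneKey.parse(row["query_key"]),
                target_key=CompositeGeneKey.parse(row["target_key"]),
                query_taxon=int(row["query_taxon"]),
                target_taxon=int(row["target_taxon"]),
                supporting_sources=frozenset((row["sources"] or "").split("|")) - {""},
                raw_assertion_ids=tuple(raw_ids),
            ))
    return OrthologTable(entries, metadata=metadata)
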