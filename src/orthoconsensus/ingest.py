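"""Reading per-source orthology assertion files and normalizing them.

Each orthology prediction resource contributes a TSV of pairwise
assertions.  An assertion names each endpoint gene in whatever namespace
the source used (a symbol, a MOD accession, an Ensembl or NCBI gene ID, a
UniProt accession); normalization resolves both endpoints through the
per-species equivalency tables onto full composite NCBI–Ensembl keys, so
that assertions from different sources about the same gene pair become
directly comparable.  Endpoints that cannot be resolved are reported, not
silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .registry import CompositeGeneKey, EquivalencyTable, Namespace

logger = logging.getLogger(__name__)

ASSERTION_COLUMNS = (
    "source", "query_taxon", "query_namespace", "query_identifier",
    "target_taxon", "target_namespace", "target_identifier", "raw_assertion_id",
)


@dataclass(frozen=True)
class SourceConfig:
    """One orthology resource: its name, data version and species coverage."""

    name: str
    version_label: str
    species_covered: frozenset[int]
    file_path: str

    def __post_init__(self) -> None:
        if not self.species_covered:
            raise ValueError(f"source {self.name!r} covers no species")


@dataclass(frozen=True)
class RawAssertion:
    """One source's orthology claim as read from its file, unresolved."""

    source: str
    query_taxon: int
    query_namespace: Namespace
    query_identifier: str
    target_taxon: int
    target_namespace: Namespace
    target_identifier: str
    raw_assertion_id: str

    def __post_init__(self) -> None:
        if self.query_taxon == self.target_taxon:
            raise ValueError("orthology assertion endpoints must differ in taxon")


@dataclass(frozen=True)
class NormalizedAssertion:
    """An assertion with both endpoints resolved to composite gene keys."""

    source: str
    query_key: CompositeGeneKey
    target_key: CompositeGeneKey
    query_taxon: int
    target_taxon: int
    raw_assertion_id: str


@dataclass(frozen=True)
class UnmappedAssertion:
    """A raw assertion that failed normalization, with the reason."""

    raw: RawAssertion
    reason: str


def read_source_file(cfg: SourceConfig) -> list[RawAssertion]:
    """Parse a source's assertion TSV; malformed rows are skipped and logged.

    A missing/incorrect header or an unknown namespace token is a hard
    failure naming the file — those indicate a mis-produced file, not a bad
    row.
    """
    path = Path(cfg.file_path)
    assertions: list[RawAssertion] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != list(ASSERTION_COLUMNS):
            raise ValueError(
                f"{path}: expected header {ASSERTION_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            for ns_col in ("query_namespace", "target_namespace"):
                token = (row.get(ns_col) or "").strip()
                try:
                    Namespace(token)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: unknown namespace token {token!r}"
                    ) from None
            try:
                assertions.append(RawAssertion(
                    source=row["source"],
                    query_taxon=int(row["query_taxon"]),
                    query_namespace=Namespace(row["query_namespace"]),
                    query_identifier=row["query_identifier"],
                    target_taxon=int(row["target_taxon"]),
                    target_namespace=Namespace(row["target_namespace"]),
                    target_identifier=row["target_identifier"],
                    raw_assertion_id=row["raw_assertion_id"],
                ))
            except (ValueError, KeyError, TypeError) as exc:
                logger.warning("%s:%d: skipped malformed assertion row (%s)",
                               path, lineno, exc)
    return assertions


def write_source_file(assertions: Iterable[RawAssertion], path: str | Path) -> int:
    path = Path(path)
    n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ASSERTION_COLUMNS)
        for a in assertions:
            writer.writerow([
                a.source, a.query_taxon, a.query_namespace.value, a.query_identifier,
                a.target_taxon, a.target_namespace.value, a.target_identifier,
                a.raw_assertion_id,
            ])
            n += 1
    return n


def normalize(
    raw: RawAssertion,
    tables: dict[int, EquivalencyTable],
) -> Optional[NormalizedAssertion]:
    """Resolve both endpoints through the equivalency tables.

    On success the assertion carries full composite keys — both IDs when
    the table knows both, even if the source named only one namespace.
    Returns ``None`` when either endpoint does not resolve; callers wanting
    the reason should use :func:`normalize_all`.
    """
    result, _ = _normalize_with_reason(raw, tables)
    return result


def _normalize_with_reason(
    raw: RawAssertion, tables: dict[int, EquivalencyTable]
) -> tuple[Optional[NormalizedAssertion], Optional[str]]:
    for side, taxon, ns, ident in (
        ("query", raw.query_taxon, raw.query_namespace, raw.query_identifier),
        ("target", raw.target_taxon, raw.target_namespace, raw.target_identifier),
    ):
        table = tables.get(taxon)
        if table is None:
            raise KeyError(f"no equivalency table for taxon {taxon}")
        if table.lookup(ns, ident) is None:
            return None, f"{side} {ns.value} identifier {ident!r} not in taxon {taxon} table"
    qrec = tables[raw.query_taxon].lookup(raw.query_namespace, raw.query_identifier)
    trec = tables[raw.target_taxon].lookup(raw.target_namespace, raw.target_identifier)
    assert qrec is not None and trec is not None
    return NormalizedAssertion(
        source=raw.source,
        query_key=qrec.composite_key(),
        target_key=trec.composite_key(),
        query_taxon=raw.query_taxon,
        target_taxon=raw.target_taxon,
        raw_assertion_id=raw.raw_assertion_id,
    ), None


def normalize_all(
    raws: Sequence[RawAssertion],
    tables: dict[int, EquivalencyTable],
) -> tuple[list[NormalizedAssertion], list[UnmappedAssertion]]:
    """Normalize a batch; unresolved assertions go to the unmapped report.

    Invariant: ``len(normalized) + len(unmapped) == len(raws)``.
    """
    normalized: list[NormalizedAssertion] = []
    unmapped: list[UnmappedAssertion] = []
    for raw in raws:
        result, reason = _normalize_with_reason(raw, tables)
        if result is None:
            assert reason is not None
            unmapped.append(UnmappedAssertion(raw, reason))
        else:
            normalized.append(result)
    return normalized, unmapped


def write_unmapped_report(unmapped: Iterable[UnmappedAssertion], path: str | Path) -> int:
    """Unmapped-assertion report: the raw row plus a reason column."""
    path = Path(path)
    n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([*ASSERTION_COLUMNS, "reason"])
        for u in unmapped:
            a = u.raw
            writer.writerow([
                a.source, a.query_taxon, a.query_namespace.value, a.query_identifier,
                a.target_taxon, a.target_namespace.value, a.target_identifier,
                a.raw_assertion_id, u.reason,
            ])
            n += 1
    return n


def dedupe_within_source(
    assertions: Sequence[NormalizedAssertion],
) -> list[NormalizedAssertion]:
    """Collapse repeated key pairs from one source.

    At most one assertion per (source, query_key, target_key) survives; the
    raw assertion IDs of merged duplicates are concatenated pipe-separated
    in sorted order.
    """
    sources = {a.source for a in assertions}
    if len(sources) > 1:
        raise ValueError(f"dedupe_within_source got multiple sources: {sorted(sources)}")
    grouped: dict[tuple, list[NormalizedAssertion]] = {}
    order: list[tuple] = []
    for a in assertions:
        k = (a.query_key, a.target_key, a.query_taxon, a.target_taxon)
        if k not in grouped:
            order.append(k)
        grouped.setdefault(k, []).append(a)
    out = []
    for k in order:
        group = grouped[k]
        ids = sorted({i for a in group for i in a.raw_assertion_id.split("|") if i})
        first = group[0]
        out.append(NormalizedAssertion(
            source=first.source,
            query_key=first.query_key,
            target_key=first.target_key,
            query_taxon=first.query_taxon,
            target_taxon=first.target_taxon,
            raw_assertion_id="|".join(ids),
        ))
    return out
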