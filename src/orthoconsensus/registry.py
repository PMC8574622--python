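"""Per-species gene identifier equivalency tables.

Every gene known to the system is identified by a *composite key*: the pair
of its NCBI Gene ID and its Ensembl stable gene ID, displayed as
``"672-ENSG00000012048"``.  Only one of the two sides needs to exist, so a
gene annotated by a single authority is still representable and orthology
assertions naming it are not lost.

A per-species :class:`EquivalencyTable` links the identifiers that the
nomenclature authorities know for each gene — the model-organism database
(MOD) accession, the Ensembl gene ID, the NCBI Gene ID and any UniProt
accessions — together with display nomenclature (symbol, name, locus type,
location).  When authorities disagree on a field, the MOD value wins, then
Ensembl, then NCBI ("coalesce priority").
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

HUMAN_TAXON = 9606

#: coalesce priority, highest first
AUTHORITY_PRIORITY = ("mod", "ensembl", "ncbi")


class Namespace(str, Enum):
    """Identifier namespaces a gene can be looked up under."""

    mod = "mod"
    ensembl = "ensembl"
    ncbi = "ncbi"
    uniprot = "uniprot"
    symbol = "symbol"


@dataclass(frozen=True)
class CompositeGeneKey:
    """NCBI Gene ID / Ensembl gene ID pair naming one gene.

    At least one side is always present.  The display form is
    ``"<ncbi>-<ensembl>"`` with an absent side rendered as empty text, e.g.
    ``"-ENSG00000999999"`` for a gene with no NCBI model.  Ensembl IDs never
    begin with a digit and NCBI IDs are purely numeric, so splitting the
    display form at the first hyphen is unambiguous.
    """

    ncbi_id: Optional[int] = None
    ensembl_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ncbi_id is None and not self.ensembl_id:
            raise ValueError("composite key needs an NCBI or an Ensembl ID")
        if self.ncbi_id is not None and self.ncbi_id <= 0:
            raise ValueError(f"NCBI Gene ID must be positive: {self.ncbi_id}")

    def display(self) -> str:
        left = "" if self.ncbi_id is None else str(self.ncbi_id)
        right = self.ensembl_id or ""
        return f"{left}-{right}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display()

    @classmethod
    def parse(cls, text: str) -> "CompositeGeneKey":
        left, _, right = text.partition("-")
        return cls(
            ncbi_id=int(left) if left else None,
            ensembl_id=right or None,
        )


@dataclass(frozen=True)
class GeneRecord:
    """One gene in one species, with all identifiers known for it.

    ``nomenclature_status`` is ``"approved"`` only when a nomenclature
    committee / MOD supplied the symbol and name; otherwise ``"gene"``,
    meaning the nomenclature was imported from Ensembl or NCBI.
    ``provenance`` records which authority supplied (or won the coalesce
    for) the row.
    """

    taxon_id: int
    symbol: str = ""
    name: str = ""
    mod_id: Optional[str] = None
    ensembl_id: Optional[str] = None
    ncbi_id: Optional[int] = None
    uniprot_ids: frozenset[str] = frozenset()
    locus_type: str = ""
    location: str = ""
    nomenclature_status: str = "gene"  # "approved" | "gene"
    provenance: str = "ensembl"  # "mod" | "ensembl" | "ncbi"

    def __post_init__(self) -> None:
        if self.nomenclature_status not in ("approved", "gene"):
            raise ValueError(f"bad nomenclature status {self.nomenclature_status!r}")
        if self.provenance not in AUTHORITY_PRIORITY:
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.nomenclature_status == "approved" and self.provenance != "mod":
            raise ValueError("approved nomenclature requires MOD provenance")

    def composite_key(self) -> CompositeGeneKey:
        return CompositeGeneKey(ncbi_id=self.ncbi_id, ensembl_id=self.ensembl_id)

    def is_protein_coding(self) -> bool:
        return self.locus_type.strip().lower() == "protein-coding gene"


def composite_key(record: GeneRecord) -> CompositeGeneKey:
    """The NCBI–Ensembl key pair identifying ``record``."""
    return record.composite_key()


class EquivalencyTable:
    """Indexed collection of merged :class:`GeneRecord` rows for one taxon."""

    def __init__(self, taxon_id: int, rows: Iterable[GeneRecord] = ()):
        self.taxon_id = taxon_id
        self.rows: list[GeneRecord] = []
        # namespace -> normalized identifier -> list of records
        self._index: dict[Namespace, dict[str, list[GeneRecord]]] = {
            ns: {} for ns in Namespace
        }
        for row in rows:
            self._add(row)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def _add(self, record: GeneRecord) -> None:
        if record.taxon_id != self.taxon_id:
            raise ValueError(
                f"record taxon {record.taxon_id} != table taxon {self.taxon_id}"
            )
        self.rows.append(record)
        if record.mod_id:
            self._index[Namespace.mod].setdefault(record.mod_id.lower(), []).append(record)
            # database prefixes are optional in queries, so index the bare
            # accession too (part after the first colon)
            _, colon, bare = record.mod_id.partition(":")
            if colon and bare:
                self._index[Namespace.mod].setdefault(bare.lower(), []).append(record)
        if record.ensembl_id:
            self._index[Namespace.ensembl].setdefault(record.ensembl_id.lower(), []).append(record)
        if record.ncbi_id is not None:
            self._index[Namespace.ncbi].setdefault(str(record.ncbi_id), []).append(record)
        for acc in record.uniprot_ids:
            self._index[Namespace.uniprot].setdefault(acc.lower(), []).append(record)
        if record.symbol:
            self._index[Namespace.symbol].setdefault(record.symbol.lower(), []).append(record)

    def lookup(self, namespace: Namespace | str, identifier: str) -> Optional[GeneRecord]:
        """Unique record indexed under ``identifier``, or ``None``.

        Symbol and UniProt hits shared by more than one gene are ambiguous:
        the lookup returns ``None`` (and logs) so that query results stay
        deterministic.
        """
        ns = Namespace(namespace)
        hits = self._index[ns].get(str(identifier).strip().lower(), [])
        if not hits:
            return None
        if len(hits) > 1:
            logger.warning(
                "ambiguous %s lookup %r in taxon %d: %d records",
                ns.value, identifier, self.taxon_id, len(hits),
            )
            return None
        return hits[0]

    def lookup_key(self, key: CompositeGeneKey) -> Optional[GeneRecord]:
        """Record whose composite key equals ``key``, if any."""
        if key.ncbi_id is not None:
            rec = self.lookup(Namespace.ncbi, str(key.ncbi_id))
            if rec is not None and rec.composite_key() == key:
                return rec
        if key.ensembl_id:
            rec = self.lookup(Namespace.ensembl, key.ensembl_id)
            if rec is not None and rec.composite_key() == key:
                return rec
        return None

    def symbols(self) -> list[str]:
        return [r.symbol for r in self.rows if r.symbol]


def lookup(
    table: EquivalencyTable, taxon_id: int, namespace: Namespace | str, identifier: str
) -> Optional[GeneRecord]:
    """Functional form of :meth:`EquivalencyTable.lookup`."""
    if table.taxon_id != taxon_id:
        raise ValueError(f"table is for taxon {table.taxon_id}, not {taxon_id}")
    return table.lookup(namespace, identifier)


# ---------------------------------------------------------------------------
# building: union-find merge + priority coalesce


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _coalesce(rows: Sequence[GeneRecord], taxon_id: int) -> GeneRecord:
    """Merge co-referent authority rows into one record, MOD > Ensembl > NCBI."""
    ranked = sorted(rows, key=lambda r: AUTHORITY_PRIORITY.index(r.provenance))

    def first(getter, default=None):
        for r in ranked:
            v = getter(r)
            if v not in (None, "", frozenset()):
                return v
        return default

    uniprot: set[str] = set()
    for r in ranked:
        uniprot |= r.uniprot_ids
    winner = ranked[0]
    status = "approved" if any(
        r.provenance == "mod" and r.nomenclature_status == "approved" for r in ranked
    ) else "gene"
    return GeneRecord(
        taxon_id=taxon_id,
        symbol=first(lambda r: r.symbol, ""),
        name=first(lambda r: r.name, ""),
        mod_id=first(lambda r: r.mod_id),
        ensembl_id=first(lambda r: r.ensembl_id),
        ncbi_id=first(lambda r: r.ncbi_id),
        uniprot_ids=frozenset(uniprot),
        locus_type=first(lambda r: r.locus_type, ""),
        location=first(lambda r: r.location, ""),
        nomenclature_status=status if winner.provenance == "mod" else "gene",
        provenance=winner.provenance,
    )


def build_equivalency(
    mod_rows: Sequence[GeneRecord],
    ensembl_rows: Sequence[GeneRecord],
    ncbi_rows: Sequence[GeneRecord],
    taxon_id: int,
) -> EquivalencyTable:
    """Build the per-species equivalency table from authority rows.

    Rows are unioned into one gene whenever they share a MOD, Ensembl or
    NCBI identifier (UniProt accessions are accumulated but never used as
    merge links — they are many-to-many against gene models).  Each merged
    gene coalesces field values preferring the MOD row, then Ensembl, then
    NCBI.  Rows carrying neither an Ensembl nor an NCBI ID (directly or via
    a MOD cross-reference in the merged group) are rejected with a logged
    reason, since they cannot form a composite key.  If two merged genes
    end up claiming the same Ensembl or NCBI ID, the gene built from the
    higher-priority authority keeps it and the ID is stripped from the
    other, both logged.
    """
    rows = [*mod_rows, *ensembl_rows, *ncbi_rows]
    for r in rows:
        if r.taxon_id != taxon_id:
            raise ValueError(f"row taxon {r.taxon_id} != build taxon {taxon_id}")

    uf = _UnionFind(len(rows))
    by_id: dict[tuple[str, str], int] = {}
    for i, r in enumerate(rows):
        for ns, ident in (("mod", r.mod_id), ("ensembl", r.ensembl_id),
                          ("ncbi", None if r.ncbi_id is None else str(r.ncbi_id))):
            if not ident:
                continue
            k = (ns, ident.lower())
            if k in by_id:
                uf.union(by_id[k], i)
            else:
                by_id[k] = i

    groups: dict[int, list[GeneRecord]] = {}
    for i, r in enumerate(rows):
        groups.setdefault(uf.find(i), []).append(r)

    merged: list[GeneRecord] = []
    for root in sorted(groups):
        rec = _coalesce(groups[root], taxon_id)
        if rec.ensembl_id is None and rec.ncbi_id is None:
            logger.warning(
                "rejected gene group (taxon %d, mod_id=%r, symbol=%r): "
                "no Ensembl or NCBI gene model to key on",
                taxon_id, rec.mod_id, rec.symbol,
            )
            continue
        merged.append(rec)

    merged = _resolve_id_conflicts(merged, taxon_id)
    merged = _dedupe_rows(merged)
    return EquivalencyTable(taxon_id, merged)


def _resolve_id_conflicts(merged: list[GeneRecord], taxon_id: int) -> list[GeneRecord]:
    """Enforce one-key-one-gene: strip duplicated Ensembl/NCBI IDs from the
    lower-priority claimant."""
    out = list(merged)
    for attr in ("ensembl_id", "ncbi_id"):
        claims: dict[object, int] = {}
        for i, rec in enumerate(out):
            ident = getattr(rec, attr)
            if ident is None:
                continue
            if ident not in claims:
                claims[ident] = i
                continue
            j = claims[ident]
            keep, drop = j, i
            if (AUTHORITY_PRIORITY.index(out[i].provenance)
                    < AUTHORITY_PRIORITY.index(out[j].provenance)):
                keep, drop = i, j
                claims[ident] = i
            logger.warning(
                "taxon %d: %s %r claimed by two genes (%r kept by %s, stripped from %r)",
                taxon_id, attr, ident, out[keep].symbol,
                out[keep].provenance, out[drop].symbol,
            )
            stripped = replace(out[drop], **{attr: None})
            if stripped.ensembl_id is None and stripped.ncbi_id is None:
                logger.warning(
                    "taxon %d: gene %r lost its last keyable ID, dropped",
                    taxon_id, stripped.symbol,
                )
                out[drop] = None  # type: ignore[call-overload]
            else:
                out[drop] = stripped
        out = [r for r in out if r is not None]
        # re-run claims for second attribute on the filtered list
    return out


def _dedupe_rows(rows: list[GeneRecord]) -> list[GeneRecord]:
    seen: set[GeneRecord] = set()
    out = []
    for r in rows:
        if r not in seen:
            seen.add(r)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# canonical gene-table TSV

GENE_TABLE_COLUMNS = (
    "taxon_id", "mod_id", "ensembl_id", "ncbi_id", "uniprot_ids",
    "symbol", "name", "locus_type", "location", "status",
)


def read_gene_table(path: str | Path, provenance: str) -> list[GeneRecord]:
    """Read one authority's canonical gene TSV (empty cells = absent)."""
    path = Path(path)
    records: list[GeneRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != list(GENE_TABLE_COLUMNS):
            raise ValueError(
                f"{path}: expected header {GENE_TABLE_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                status = (row["status"] or "gene").strip().lower()
                records.append(GeneRecord(
                    taxon_id=int(row["taxon_id"]),
                    mod_id=row["mod_id"] or None,
                    ensembl_id=row["ensembl_id"] or None,
                    ncbi_id=int(row["ncbi_id"]) if row["ncbi_id"] else None,
                    uniprot_ids=frozenset(
                        a for a in (row["uniprot_ids"] or "").split("|") if a
                    ),
                    symbol=row["symbol"] or "",
                    name=row["name"] or "",
                    locus_type=row["locus_type"] or "",
                    location=row["location"] or "",
                    nomenclature_status=status,
                    provenance=provenance,
                ))
            except (ValueError, KeyError) as exc:
                logger.warning("%s:%d: skipped malformed gene row (%s)", path, lineno, exc)
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> int:
    """Write records in the canonical gene TSV layout; returns row count."""
    path = Path(path)
    n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for r in records:
            writer.writerow([
                r.taxon_id,
                r.mod_id or "",
                r.ensembl_id or "",
                "" if r.ncbi_id is None else r.ncbi_id,
                "|".join(sorted(r.uniprot_ids)),
                r.symbol,
                r.name,
                r.locus_type,
                r.location,
                r.nomenclature_status,
            ])
            n += 1
    return n
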