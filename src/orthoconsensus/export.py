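"""Bulk download formats for combined ortholog data.

Two pairwise layouts are produced: a 6-column file carrying just the
composite-key identifiers, supporting sources and raw assertion IDs, and a
15-column file that adds nomenclature (MOD ID, name, symbol, location) for
both genes.  Each layout also has an all-species variant with a leading
ortholog-taxon-ID column.  Output is deterministic: rows and source lists
are sorted, missing values are written as ``"-"``, files are UTF-8 TSV
with Unix newlines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .aggregate import CombinedOrtholog, OrthologTable
from .registry import CompositeGeneKey, EquivalencyTable, GeneRecord

MISSING = "-"

SIX_COLUMN_HEADER = (
    "human_ncbi_id", "human_ensembl_id",
    "ortholog_ncbi_id", "ortholog_ensembl_id",
    "support", "raw_assertion_ids",
)

FIFTEEN_COLUMN_HEADER = (
    "human_ncbi_id", "human_ensembl_id", "human_mod_id", "human_name",
    "human_symbol", "human_location", "human_raw_assertion_ids",
    "ortholog_ncbi_id", "ortholog_ensembl_id", "ortholog_mod_id",
    "ortholog_name", "ortholog_symbol", "ortholog_location",
    "ortholog_raw_assertion_ids", "support",
)


@dataclass(frozen=True)
class ExportSpec:
    mode: str  # "six_column" | "fifteen_column"
    scope: str = "single_species_pair"  # | "all_species"
    target_taxon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("six_column", "fifteen_column"):
            raise ValueError(f"unknown export mode {self.mode!r}")
        if self.scope not in ("single_species_pair", "all_species"):
            raise ValueError(f"unknown export scope {self.scope!r}")
        if self.scope == "single_species_pair" and self.target_taxon is None:
            raise ValueError("single-species export requires a target taxon")


def _cell(value) -> str:
    if value is None or value == "":
        return MISSING
    return str(value)


def _sorted_entries(table: OrthologTable, taxon: Optional[int]) -> list[CombinedOrtholog]:
    entries = [
        e for e in table
        if taxon is None or e.target_taxon == taxon
    ]
    return sorted(
        entries,
        key=lambda e: (e.target_taxon, e.query_key.display(), e.target_key.display()),
    )


def _six_column_row(e: CombinedOrtholog) -> list[str]:
    return [
        _cell(e.query_key.ncbi_id),
        _cell(e.query_key.ensembl_id),
        _cell(e.target_key.ncbi_id),
        _cell(e.target_key.ensembl_id),
        ",".join(sorted(e.supporting_sources)),
        _cell(e.all_raw_ids()),
    ]


def _fifteen_column_row(
    e: CombinedOrtholog, registry: dict[int, EquivalencyTable]
) -> list[str]:
    def side(key: CompositeGeneKey, taxon: int) -> list[str]:
        rec: Optional[GeneRecord] = None
        if taxon in registry:
            rec = registry[taxon].lookup_key(key)
        return [
            _cell(key.ncbi_id),
            _cell(key.ensembl_id),
            _cell(rec.mod_id if rec else None),
            _cell(rec.name if rec else None),
            _cell(rec.symbol if rec else None),
            _cell(rec.location if rec else None),
            _cell(e.all_raw_ids()),
        ]

    return (
        side(e.query_key, e.query_taxon)
        + side(e.target_key, e.target_taxon)
        + [",".join(sorted(e.supporting_sources))]
    )


def write_six_column(table: OrthologTable, spec: ExportSpec, out: str | Path) -> int:
    """Write the 6-column pairwise file; returns the data-row count."""
    if spec.mode != "six_column":
        raise ValueError("spec.mode must be six_column")
    entries = _sorted_entries(table, spec.target_taxon)
    with Path(out).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SIX_COLUMN_HEADER)
        for e in entries:
            writer.writerow(_six_column_row(e))
    return len(entries)


def write_fifteen_column(
    table: OrthologTable,
    registry: dict[int, EquivalencyTable],
    spec: ExportSpec,
    out: str | Path,
) -> int:
    """Write the 15-column annotated pairwise file; returns the row count."""
    if spec.mode != "fifteen_column":
        raise ValueError("spec.mode must be fifteen_column")
    entries = _sorted_entries(table, spec.target_taxon)
    with Path(out).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FIFTEEN_COLUMN_HEADER)
        for e in entries:
            writer.writerow(_fifteen_column_row(e, registry))
    return len(entries)


def write_all_species(
    table: OrthologTable,
    registry: dict[int, EquivalencyTable],
    spec: ExportSpec,
    out: str | Path,
) -> int:
    """Write the all-species file: chosen layout plus leading ortholog taxon ID.

    Rows are sorted by ortholog taxon, then human key — so cutting the file
    on the first column reproduces the per-species exports exactly.
    """
    if spec.scope != "all_species":
        raise ValueError("spec.scope must be all_species")
    entries = _sorted_entries(table, None)
    if spec.mode == "six_column":
        header = ("ortholog_taxon_id", *SIX_COLUMN_HEADER)
        make_row = lambda e: [str(e.target_taxon)] + _six_column_row(e)
    else:
        header = ("ortholog_taxon_id", *FIFTEEN_COLUMN_HEADER)
        make_row = lambda e: [str(e.target_taxon)] + _fifteen_column_row(e, registry)
    with Path(out).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for e in entries:
            writer.writerow(make_row(e))
    return len(entries)


def write_query_results(panels, out: str | Path) -> int:
    """Per-query result download: one TSV row per (query gene, ortholog)."""
    header = (
        "query_term", "query_symbol", "query_key",
        "ortholog_taxon", "ortholog_symbol", "ortholog_key",
        "nomenclature", "support_count", "sources",
    )
    n = 0
    with Path(out).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for panel in panels:
            for entry, rec, label in panel.orthologs:
                other_key = (entry.target_key if panel.query_gene.taxon_id == entry.query_taxon
                             else entry.query_key)
                other_taxon = (entry.target_taxon if panel.query_gene.taxon_id == entry.query_taxon
                               else entry.query_taxon)
                writer.writerow([
                    panel.query_term,
                    _cell(panel.query_gene.symbol),
                    panel.query_gene.composite_key().display(),
                    other_taxon,
                    _cell(rec.symbol if rec else None),
                    other_key.display(),
                    label,
                    entry.support_count(),
                    ",".join(sorted(entry.supporting_sources)),
                ])
                n += 1
    return n
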