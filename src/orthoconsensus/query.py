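"""Search semantics: term splitting, prefix stripping, wildcards, panels.

Queries accept lists of terms separated by commas, whitespace or newlines,
searched case-insensitively.  Database identifier prefixes ("HGNC:",
"MGI:", "ZFIN", ...) are optional — a search works whether they are
included or not.  Symbol queries support wildcards: ``_`` substitutes for
a single character, and ``*`` or ``%`` substitute for one or more
characters (so ``ABCA*`` matches ``ABCA1`` but not ``ABCA`` itself).
Non-human query genes can only be matched against their human orthologs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .aggregate import CombinedOrtholog, OrthologTable, results_for
from .registry import (
    HUMAN_TAXON,
    CompositeGeneKey,
    EquivalencyTable,
    GeneRecord,
    Namespace,
)

# prefixes always written with a colon, and those that may appear bare
_COLON_PREFIXES = ("HGNC", "VGNC", "MGI", "RGD", "SGD", "BGD", "CGNC",
                   "WB", "XB", "ZDB")
_BARE_PREFIXES = ("ZFIN", "XENBASE")

_SPLIT_RE = re.compile(r"[,\s]+")


class QueryType:
    symbol = "symbol"
    name_contains = "name_contains"
    mod_id = "mod_id"
    ensembl_id = "ensembl_id"
    ncbi_id = "ncbi_id"
    uniprot_id = "uniprot_id"

    all = (symbol, name_contains, mod_id, ensembl_id, ncbi_id, uniprot_id)


_TYPE_TO_NAMESPACE = {
    QueryType.symbol: Namespace.symbol,
    QueryType.mod_id: Namespace.mod,
    QueryType.ensembl_id: Namespace.ensembl,
    QueryType.ncbi_id: Namespace.ncbi,
    QueryType.uniprot_id: Namespace.uniprot,
}


@dataclass
class QuerySpec:
    """One search: which gene(s), from/to which species, which sources.

    By default the query species is human with every species targeted and
    every source included.  For a non-human query species only human
    orthologs are returned.
    """

    terms: list[str]
    query_taxon: int = HUMAN_TAXON
    target_taxa: Optional[set[int]] = None  # None = all available
    query_type: str = QueryType.symbol
    included_sources: Optional[set[str]] = None  # None = all configured

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("query needs at least one term")
        if self.query_type not in QueryType.all:
            raise ValueError(f"unknown query type {self.query_type!r}")
        if self.query_taxon != HUMAN_TAXON:
            if self.target_taxa not in (None, {HUMAN_TAXON}):
                raise ValueError(
                    "non-human query genes can only be matched to human orthologs"
                )
            self.target_taxa = {HUMAN_TAXON}


@dataclass
class ResultPanel:
    """One query gene with its ordered orthologs and provenance labels.

    The nomenclature label is ``"Approved"`` when the gene's symbol and
    name come from a nomenclature committee / MOD, ``"Gene"`` when they
    were imported from Ensembl or NCBI.
    """

    query_term: str
    query_gene: GeneRecord
    orthologs: list[tuple[CombinedOrtholog, Optional[GeneRecord], str]]

    @staticmethod
    def label_for(record: Optional[GeneRecord]) -> str:
        if record is not None and record.nomenclature_status == "approved":
            return "Approved"
        return "Gene"


def split_terms(raw_input: str) -> list[str]:
    """Split multi-term input on any run of commas, spaces or newlines."""
    return [t for t in _SPLIT_RE.split(raw_input) if t]


def strip_prefix(term: str) -> str:
    """Remove one leading database prefix, if present (case-insensitive)."""
    upper = term.upper()
    for prefix in _COLON_PREFIXES:
        if upper.startswith(prefix + ":"):
            return term[len(prefix) + 1:]
    for prefix in _BARE_PREFIXES:
        if upper.startswith(prefix + ":"):
            return term[len(prefix) + 1:]
        if upper.startswith(prefix):
            return term[len(prefix):]
    return term


_WILDCARD_CHARS = set("_*%")


def has_wildcard(pattern: str) -> bool:
    return any(c in _WILDCARD_CHARS for c in pattern)


def _wildcard_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        if ch == "_":
            parts.append(".")
        elif ch in "*%":
            parts.append(".+")  # one or more, not zero-or-more
        else:
            parts.append(re.escape(ch))
    return re.compile("".join(parts), re.IGNORECASE)


def wildcard_match(pattern: str, symbols: Iterable[str]) -> set[str]:
    """Symbols matching ``pattern`` case-insensitively.

    ``_`` matches exactly one character; ``*`` and ``%`` match one or more.
    A pattern without wildcards requires whole-string equality.
    """
    if not has_wildcard(pattern):
        want = pattern.lower()
        return {s for s in symbols if s.lower() == want}
    rx = _wildcard_regex(pattern)
    return {s for s in symbols if rx.fullmatch(s)}


def _expand_term(
    term: str, query_type: str, registry: EquivalencyTable
) -> list[GeneRecord]:
    """Resolve one term to the concrete gene records it denotes."""
    if query_type == QueryType.name_contains:
        needle = term.lower()
        return [r for r in registry if needle in r.name.lower()]
    if query_type == QueryType.symbol and has_wildcard(term):
        matched = wildcard_match(term, registry.symbols())
        records = []
        for sym in sorted(matched, key=str.lower):
            rec = registry.lookup(Namespace.symbol, sym)
            if rec is not None:
                records.append(rec)
        return records
    ns = _TYPE_TO_NAMESPACE[query_type]
    lookup_term = term
    if ns in (Namespace.mod, Namespace.symbol):
        # prefixes are optional either way: try verbatim, then stripped
        rec = registry.lookup(ns, lookup_term)
        if rec is None:
            rec = registry.lookup(ns, strip_prefix(term))
    else:
        rec = registry.lookup(ns, lookup_term)
    return [rec] if rec is not None else []


def run_query(
    spec: QuerySpec,
    registries: dict[int, EquivalencyTable],
    table: OrthologTable,
) -> list[ResultPanel]:
    """Run a search and build one result panel per matching query gene.

    Wildcard and name-contains terms first expand to the concrete genes
    they denote; each distinct gene with at least one ortholog in the
    requested target species yields a panel.  Within a panel, orthologs are
    ordered by support count (most-supported first per species).
    """
    registry = registries.get(spec.query_taxon)
    if registry is None:
        raise KeyError(f"no registry for query taxon {spec.query_taxon}")
    target_taxa = spec.target_taxa
    if target_taxa is None:
        target_taxa = table.target_taxa() | {
            t for t in registries if t != spec.query_taxon
        }
    included = spec.included_sources
    if included is None:
        included = {s for e in table for s in e.supporting_sources}

    panels: list[ResultPanel] = []
    seen_genes: set[CompositeGeneKey] = set()
    for term in spec.terms:
        for gene in _expand_term(term, spec.query_type, registry):
            key = gene.composite_key()
            if key in seen_genes:
                continue
            seen_genes.add(key)
            if spec.query_taxon == HUMAN_TAXON:
                entries = results_for(table, key, target_taxa, included, registries)
                ortho_side = [(e, e.target_key, e.target_taxon) for e in entries]
            else:
                entries = _human_results_for_target(table, key, included)
                ortho_side = [(e, e.query_key, e.query_taxon) for e in entries]
            if not entries:
                continue
            orthologs = []
            for entry, okey, otaxon in ortho_side:
                rec = None
                if otaxon in registries:
                    rec = registries[otaxon].lookup_key(okey)
                orthologs.append((entry, rec, ResultPanel.label_for(rec)))
            panels.append(ResultPanel(term, gene, orthologs))
    return panels


def _human_results_for_target(
    table: OrthologTable,
    gene_key: CompositeGeneKey,
    included_sources: set[str],
) -> list[CombinedOrtholog]:
    """Human orthologs of a non-human gene, ordered by support."""
    hits = [
        e for e in table.entries_for_target(gene_key)
        if e.supporting_sources & included_sources
    ]
    return sorted(hits, key=lambda e: (-e.support_count(), e.query_key.display()))
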