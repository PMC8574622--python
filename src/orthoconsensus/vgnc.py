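"""High-confidence ortholog screen for vertebrate nomenclature transfer.

The Vertebrate Gene Nomenclature Committee (VGNC) names genes in species
without their own committee by transferring nomenclature from the human
ortholog.  A combined ortholog qualifies as *high confidence* when it is a
one-to-one relationship between protein-coding genes and is predicted by
at least three of the four voting resources (Ensembl, NCBI Gene, OMA and
PANTHER).  When all four voters agree and a set of additional curator
checks passes, the human symbol and name are transferred automatically;
a candidate with three voters, or failing an extra check, is flagged for
manual curation; everything else is rejected.

The curators' full rule set is not public; :func:`default_extra_checks`
is this package's stand-in (approved human nomenclature, no placeholder
"orf" symbol) and any predicate can be injected in its place.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from .aggregate import CombinedOrtholog, OrthologTable
from .registry import CompositeGeneKey, EquivalencyTable, GeneRecord

#: the four voting resources of the high-confidence screen
DEFAULT_VOTERS = frozenset({"Ensembl", "NCBI Gene", "OMA", "PANTHER"})

PROTEIN_CODING = "protein-coding gene"

_ORF_PLACEHOLDER = re.compile(r"orf\d+$", re.IGNORECASE)


@dataclass(frozen=True)
class HighConfidenceCall:
    """A combined ortholog classified under the nomenclature-transfer rule."""

    entry: CombinedOrtholog
    voter_support: frozenset[str]
    is_one_to_one: bool
    both_protein_coding: bool
    extra_checks_passed: bool
    classification: str  # "auto_name" | "manual_curation" | "rejected"
    reasons: tuple[str, ...] = ()


def _voter_set(entry: CombinedOrtholog, voters: frozenset[str]) -> frozenset[str]:
    lowered = {v.lower(): v for v in voters}
    return frozenset(
        lowered[s.lower()] for s in entry.supporting_sources if s.lower() in lowered
    )


def one_to_one_status(
    table: OrthologTable,
    entry: CombinedOrtholog,
    voters: frozenset[str] = DEFAULT_VOTERS,
) -> bool:
    """Whether the pair is one-to-one among voter-supported entries.

    Restricted to the entry's species pair and to entries supported by at
    least one voting resource: true iff the human gene maps to no other
    target gene and the target gene maps to no other human gene.
    """
    lowered = {v.lower() for v in voters}

    def voter_supported(e: CombinedOrtholog) -> bool:
        return any(s.lower() in lowered for s in e.supporting_sources)

    slice_ = [
        e for e in table
        if e.target_taxon == entry.target_taxon and voter_supported(e)
    ]
    human_degree = sum(1 for e in slice_ if e.query_key == entry.query_key)
    target_degree = sum(1 for e in slice_ if e.target_key == entry.target_key)
    return human_degree == 1 and target_degree == 1


def default_extra_checks(human: Optional[GeneRecord]) -> tuple[bool, list[str]]:
    """Stand-in for the curators' transfer-suitability rules."""
    reasons = []
    if human is None:
        reasons.append("human gene not found in registry")
    else:
        if not human.symbol:
            reasons.append("human gene has no symbol")
        if human.nomenclature_status != "approved":
            reasons.append("human symbol is not committee-approved")
        if human.symbol and _ORF_PLACEHOLDER.search(human.symbol):
            reasons.append("placeholder 'orf' symbol is not transferable")
    return not reasons, reasons


def classify(
    table: OrthologTable,
    entry: CombinedOrtholog,
    locus_types: Callable[[CompositeGeneKey, int], Optional[str]],
    extra_checks: Optional[Callable[[CombinedOrtholog], tuple[bool, list[str]]]] = None,
    voters: frozenset[str] = DEFAULT_VOTERS,
    human_record: Optional[GeneRecord] = None,
) -> HighConfidenceCall:
    """Apply the high-confidence gate and the auto/manual/reject decision.

    Gate: one-to-one ∧ both genes protein-coding ∧ ≥3 of the 4 voters.
    Passing with all 4 voters and clean extra checks yields ``auto_name``;
    passing otherwise yields ``manual_curation``; failing the gate yields
    ``rejected``.  ``reasons`` lists every failed condition.
    """
    support = _voter_set(entry, voters)
    one_to_one = one_to_one_status(table, entry, voters)

    def coding(key: CompositeGeneKey, taxon: int) -> bool:
        lt = locus_types(key, taxon)
        return (lt or "").strip().lower() == PROTEIN_CODING

    both_coding = (coding(entry.query_key, entry.query_taxon)
                   and coding(entry.target_key, entry.target_taxon))

    reasons: list[str] = []
    if len(support) < 3:
        reasons.append(
            f"only {len(support)} of {len(voters)} voting resources support the pair"
        )
    if not one_to_one:
        reasons.append("not a one-to-one relationship among voter-supported pairs")
    if not both_coding:
        reasons.append("both genes must be protein-coding")

    gate_passed = not reasons

    if extra_checks is not None:
        checks_ok, check_reasons = extra_checks(entry)
    elif human_record is not None:
        checks_ok, check_reasons = default_extra_checks(human_record)
    else:
        checks_ok, check_reasons = True, []

    if not gate_passed:
        classification = "rejected"
    elif len(support) == len(voters) and checks_ok:
        classification = "auto_name"
    else:
        classification = "manual_curation"
        if len(support) < len(voters):
            reasons.append("fewer than four voting resources confirm the assignment")
        if not checks_ok:
            reasons.extend(check_reasons)

    return HighConfidenceCall(
        entry=entry,
        voter_support=support,
        is_one_to_one=one_to_one,
        both_protein_coding=both_coding,
        extra_checks_passed=checks_ok,
        classification=classification,
        reasons=tuple(reasons),
    )


def transfer_nomenclature(human: GeneRecord, target: GeneRecord) -> tuple[str, str]:
    """Proposed (symbol, name) for the target gene: the human nomenclature.

    Only committee-approved human nomenclature may be transferred; a human
    record with imported ("gene") status is refused.
    """
    if human.nomenclature_status != "approved":
        raise ValueError(
            f"human nomenclature for {human.symbol or human.composite_key()} "
            "is not committee-approved; refusing transfer"
        )
    return human.symbol, human.name


def screen_species_pair(
    table: OrthologTable,
    registries: dict[int, EquivalencyTable],
    target_taxon: int,
    voters: frozenset[str] = DEFAULT_VOTERS,
    extra_checks: Optional[Callable] = None,
) -> list[HighConfidenceCall]:
    """Classify every combined ortholog for one human–target species pair."""

    def locus_types(key: CompositeGeneKey, taxon: int) -> Optional[str]:
        reg = registries.get(taxon)
        if reg is None:
            return None
        rec = reg.lookup_key(key)
        return rec.locus_type if rec else None

    calls = []
    human_reg = registries.get(9606)
    for entry in table:
        if entry.target_taxon != target_taxon:
            continue
        human_rec = human_reg.lookup_key(entry.query_key) if human_reg else None
        calls.append(classify(
            table, entry, locus_types,
            extra_checks=extra_checks, voters=voters, human_record=human_rec,
        ))
    return calls


def write_screen_report(calls: Iterable[HighConfidenceCall], out: str | Path) -> int:
    header = ("human_key", "target_key", "voters", "classification", "reasons")
    n = 0
    with Path(out).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for c in sorted(
            calls,
            key=lambda c: (c.entry.query_key.display(), c.entry.target_key.display()),
        ):
            writer.writerow([
                c.entry.query_key.display(),
                c.entry.target_key.display(),
                ",".join(sorted(c.voter_support)),
                c.classification,
                "; ".join(c.reasons) or "-",
            ])
            n += 1
    return n
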