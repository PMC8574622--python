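"""Seeded synthetic gene tables and orthology assertion files.

The generator fabricates a small multi-species world with known ground
truth: per-taxon gene complements with realistically shaped identifiers
(``ENSG``/``ENSMUSG`` + 11 digits, numeric NCBI Gene IDs, prefixed MOD
accessions), one-to-one ortholog pairs between human and every other
species (a configurable fraction of human genes get a second co-ortholog),
and per-source assertion files in which each source independently recovers
a true pair with probability ``concordance``.  A non-concordant source
either omits the pair or, half the time, asserts a wrong partner — the two
failure modes seen in real aggregations (missing annotation, outdated
assemblies).  Identifier-coverage gaps (Ensembl-only or NCBI-only genes)
and partial MOD coverage are planted at configurable rates so key
construction and prefix handling are exercised.

Everything is deterministic given the seed, and the generator writes a
build config consumable by the pipeline, so the whole stack can be tested
without downloading anything.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .aggregate import OrthologTable
from .registry import (
    HUMAN_TAXON,
    GeneRecord,
    write_gene_table,
)
from .ingest import RawAssertion, write_source_file
from .registry import Namespace

# identifier shapes per taxon: (Ensembl prefix, MOD prefix)
_TAXON_STYLE = {
    9606: ("ENSG", "HGNC"),
    10090: ("ENSMUSG", "MGI"),
    10116: ("ENSRNOG", "RGD"),
    9031: ("ENSGALG", "CGNC"),
    7955: ("ENSDARG", "ZDB"),
    9615: ("ENSCAFG", "VGNC"),
}

#: default source roster: the four voting resources plus eight more, mirroring
#: a twelve-source human-mouse aggregation
DEFAULT_SOURCE_NAMES = (
    "Ensembl", "NCBI Gene", "OMA", "PANTHER",
    "eggNOG", "HomoloGene", "Inparanoid", "OrthoDB",
    "OrthoMCL", "PhylomeDB", "TreeFam", "HGNC",
)


@dataclass
class SimConfig:
    """Conditions of one synthetic world.

    ``concordance`` is the probability that a source recovers a true
    ortholog pair; ``dup_rate`` the probability a human gene carries a
    second co-ortholog in a target species (real aggregations report ~5%
    of unanimously supported genes with more than one putative ortholog);
    ``ensembl_only_rate``/``ncbi_only_rate`` the probabilities a gene lacks
    the other authority's gene model; ``mod_coverage`` the probability a
    gene has a MOD/nomenclature-committee record.
    """

    seed: int = 0
    taxa: tuple[int, ...] = (9606, 10090)  # human first
    genes_per_taxon: int = 200
    n_sources: int = 12
    concordance: float = 0.9
    dup_rate: float = 0.05
    ensembl_only_rate: float = 0.05
    ncbi_only_rate: float = 0.05
    mod_coverage: float = 0.9
    noncoding_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("concordance", "dup_rate", "ensembl_only_rate",
                     "ncbi_only_rate", "mod_coverage", "noncoding_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.genes_per_taxon < 1:
            raise ValueError("genes_per_taxon must be >= 1")
        if self.taxa[0] != HUMAN_TAXON:
            raise ValueError("taxa must start with human (9606)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")


@dataclass
class SimGene:
    taxon: int
    index: int
    symbol: str
    name: str
    mod_id: Optional[str]
    ensembl_id: Optional[str]
    ncbi_id: Optional[int]
    uniprot: str
    locus_type: str

    def identifier(self, ns: Namespace) -> Optional[str]:
        return {
            Namespace.mod: self.mod_id,
            Namespace.ensembl: self.ensembl_id,
            Namespace.ncbi: None if self.ncbi_id is None else str(self.ncbi_id),
            Namespace.uniprot: self.uniprot,
            Namespace.symbol: self.symbol,
        }[ns]

    def namespaces(self) -> list[Namespace]:
        return [ns for ns in (Namespace.ensembl, Namespace.ncbi, Namespace.mod,
                              Namespace.symbol, Namespace.uniprot)
                if self.identifier(ns)]


@dataclass
class GroundTruth:
    """What the generator planted, for assertion-level checks in tests."""

    genes: dict[int, list[SimGene]]
    #: per non-human taxon: list of (human index, target index) true pairs
    true_pairs: dict[int, list[tuple[int, int]]]
    #: per source name: emitted (taxon, human index, target index, is_error)
    emitted: dict[str, list[tuple[int, int, int, bool]]]
    config_path: Path

    def true_pair_count(self) -> int:
        return sum(len(v) for v in self.true_pairs.values())


def _make_genes(cfg: SimConfig, taxon: int, n: int, rng: random.Random) -> list[SimGene]:
    ens_prefix, mod_prefix = _TAXON_STYLE.get(taxon, (f"ENSX{taxon % 97}G", "MOD"))
    genes = []
    for i in range(n):
        root = f"SYM{i + 1}"
        symbol = root if taxon == HUMAN_TAXON else root.capitalize()
        ensembl = f"{ens_prefix}{taxon % 100:02d}{i + 1:09d}"
        ncbi = taxon * 1000 + i + 1
        has_mod = rng.random() < cfg.mod_coverage
        u = rng.random()
        if u < cfg.ensembl_only_rate:
            ncbi = None
        elif u < cfg.ensembl_only_rate + cfg.ncbi_only_rate:
            ensembl = None
        locus = ("protein-coding gene" if rng.random() >= cfg.noncoding_rate
                 else rng.choice(["pseudogene", "RNA, long non-coding"]))
        genes.append(SimGene(
            taxon=taxon,
            index=i,
            symbol=symbol,
            name=f"synthetic gene {root} ({taxon})",
            mod_id=f"{mod_prefix}:{10000 + i}" if has_mod else None,
            ensembl_id=ensembl,
            ncbi_id=ncbi,
            uniprot=f"P{taxon % 10}{i + 1:04d}",
            locus_type=locus,
        ))
    return genes


def _gene_record(g: SimGene, provenance: str) -> GeneRecord:
    approved = provenance == "mod"
    return GeneRecord(
        taxon_id=g.taxon,
        mod_id=g.mod_id if provenance == "mod" else None,
        ensembl_id=g.ensembl_id,
        ncbi_id=g.ncbi_id,
        uniprot_ids=frozenset({g.uniprot}) if provenance != "ncbi" else frozenset(),
        symbol=g.symbol,
        name=g.name,
        locus_type=g.locus_type,
        location=f"{(g.index % 22) + 1}q{(g.index % 30) + 1}",
        nomenclature_status="approved" if approved else "gene",
        provenance=provenance,
    )


def simulate(cfg: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Write fixture files under ``out_dir`` and return the ground truth.

    Emits, per taxon, up to three authority gene TSVs (MOD rows only for
    genes with MOD coverage), one assertion TSV per source, and a
    ``config.yaml`` the pipeline can build from.  Byte-identical across
    runs with the same config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)

    # gene complements; non-human taxa get extra genes to serve as planted
    # co-orthologs
    genes: dict[int, list[SimGene]] = {}
    true_pairs: dict[int, list[tuple[int, int]]] = {}
    for taxon in cfg.taxa:
        n = cfg.genes_per_taxon
        if taxon != HUMAN_TAXON:
            n += max(1, int(cfg.genes_per_taxon * cfg.dup_rate) + 1)
        genes[taxon] = _make_genes(cfg, taxon, n, rng)

    for taxon in cfg.taxa[1:]:
        pairs = [(i, i) for i in range(cfg.genes_per_taxon)]
        extra_start = cfg.genes_per_taxon
        n_extra = len(genes[taxon]) - cfg.genes_per_taxon
        k = 0
        for i in range(cfg.genes_per_taxon):
            if k >= n_extra:
                break
            if rng.random() < cfg.dup_rate:
                pairs.append((i, extra_start + k))
                k += 1
        true_pairs[taxon] = pairs

    # authority gene tables
    species_cfg = []
    for taxon in cfg.taxa:
        entry: dict = {"taxon_id": taxon, "name": str(taxon)}
        mod_rows = [_gene_record(g, "mod") for g in genes[taxon] if g.mod_id]
        ens_rows = [_gene_record(g, "ensembl") for g in genes[taxon] if g.ensembl_id]
        ncbi_rows = [_gene_record(g, "ncbi") for g in genes[taxon] if g.ncbi_id]
        if mod_rows:
            p = out_dir / f"genes_{taxon}_mod.tsv"
            write_gene_table(mod_rows, p)
            entry["mod_file"] = p.name
        p = out_dir / f"genes_{taxon}_ensembl.tsv"
        write_gene_table(ens_rows, p)
        entry["ensembl_file"] = p.name
        p = out_dir / f"genes_{taxon}_ncbi.tsv"
        write_gene_table(ncbi_rows, p)
        entry["ncbi_file"] = p.name
        species_cfg.append(entry)

    # per-source assertions
    source_names = list(DEFAULT_SOURCE_NAMES[:cfg.n_sources])
    while len(source_names) < cfg.n_sources:
        source_names.append(f"Source{len(source_names) + 1}")
    emitted: dict[str, list[tuple[int, int, int, bool]]] = {s: [] for s in source_names}
    sources_cfg = []
    for source in source_names:
        raws: list[RawAssertion] = []
        counter = 0
        for taxon in cfg.taxa[1:]:
            for (hi, ti) in true_pairs[taxon]:
                hgene = genes[HUMAN_TAXON][hi]
                tgene = genes[taxon][ti]
                if rng.random() < cfg.concordance:
                    partner, is_error = tgene, False
                elif rng.random() < 0.5:
                    wrong = rng.randrange(len(genes[taxon]) - 1)
                    if wrong >= ti:
                        wrong += 1
                    partner, is_error = genes[taxon][wrong], True
                else:
                    continue  # source misses the pair entirely
                counter += 1
                q_ns = rng.choice(hgene.namespaces())
                t_ns = rng.choice(partner.namespaces())
                raws.append(RawAssertion(
                    source=source,
                    query_taxon=HUMAN_TAXON,
                    query_namespace=q_ns,
                    query_identifier=hgene.identifier(q_ns),
                    target_taxon=taxon,
                    target_namespace=t_ns,
                    target_identifier=partner.identifier(t_ns),
                    raw_assertion_id=f"{source[:3].upper()}{counter:06d}",
                ))
                emitted[source].append((taxon, hi, partner.index, is_error))
        p = out_dir / f"assertions_{source.replace(' ', '_')}.tsv"
        write_source_file(raws, p)
        sources_cfg.append({
            "name": source,
            "version_label": "sim-1",
            "species": list(cfg.taxa),
            "file": p.name,
        })

    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(
        {"species": species_cfg, "sources": sources_cfg, "artifacts_dir": "artifacts"},
        sort_keys=False,
    ))
    return GroundTruth(genes=genes, true_pairs=true_pairs, emitted=emitted,
                       config_path=config_path)


def concordance_report(
    table: OrthologTable,
    n_sources: int,
    n_human_genes: Optional[int] = None,
    target_taxon: Optional[int] = None,
) -> dict:
    """Support-threshold profile over human genes.

    For each k in 1..n_sources, the fraction of human genes with at least
    one ortholog supported by >= k sources; plus the unanimous fraction
    (>= 1 ortholog supported by all sources) and, among unanimous genes,
    the fraction with more than one putative ortholog.  The denominator
    defaults to the number of distinct human genes in the table.
    """
    entries = [e for e in table
               if target_taxon is None or e.target_taxon == target_taxon]
    best: dict = {}
    unanimous_orthologs: dict = {}
    for e in entries:
        k = e.query_key
        best[k] = max(best.get(k, 0), e.support_count())
        if e.support_count() >= n_sources:
            unanimous_orthologs[k] = unanimous_orthologs.get(k, 0) + 1
    denom = n_human_genes if n_human_genes is not None else len(best)
    if denom == 0:
        return {
            "fractions_by_threshold": {k: 0.0 for k in range(1, n_sources + 1)},
            "unanimous_fraction": 0.0,
            "unanimous_multi_ortholog_fraction": 0.0,
        }
    fractions = {
        k: sum(1 for v in best.values() if v >= k) / denom
        for k in range(1, n_sources + 1)
    }
    n_unanimous = len(unanimous_orthologs)
    multi = sum(1 for v in unanimous_orthologs.values() if v > 1)
    return {
        "fractions_by_threshold": fractions,
        "unanimous_fraction": n_unanimous / denom,
        "unanimous_multi_ortholog_fraction": (multi / n_unanimous) if n_unanimous else 0.0,
    }
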