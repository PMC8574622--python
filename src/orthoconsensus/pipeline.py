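"""End-to-end build orchestration with content-hash change detection.

The build has three artifact layers: per-species equivalency tables, per-
source normalized assertions, and per-target-species combined ortholog
tables.  Every input file is fingerprinted (SHA-256 of content, not
mtime, so runs are reproducible); an artifact is stale exactly when an
upstream fingerprint differs from the one recorded at its last build.
A nomenclature change for one species regenerates that species'
equivalency table, re-normalizes every source covering the species and
re-combines the affected species pairs; untouched species pairs are not
rebuilt.  Executing the resulting plan always converges to the same
artifacts as a from-scratch build.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import ingest
from .aggregate import OrthologTable, combine, read_snapshot, write_snapshot
from .ingest import NormalizedAssertion, SourceConfig
from .registry import (
    HUMAN_TAXON,
    CompositeGeneKey,
    EquivalencyTable,
    GeneRecord,
    build_equivalency,
    read_gene_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


class SpeciesEntry(BaseModel):
    taxon_id: int
    name: str = ""
    mod_file: Optional[str] = None
    ensembl_file: Optional[str] = None
    ncbi_file: Optional[str] = None

    @model_validator(mode="after")
    def _at_least_one_authority(self):
        if not (self.mod_file or self.ensembl_file or self.ncbi_file):
            raise ValueError(f"species {self.taxon_id} declares no gene tables")
        return self


class SourceEntry(BaseModel):
    name: str
    version_label: str = ""
    species: list[int]
    file: str

    @field_validator("species")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("source must cover at least one species")
        return v


class PipelineConfig(BaseModel):
    species: list[SpeciesEntry]
    sources: list[SourceEntry]
    artifacts_dir: str = "artifacts"

    @model_validator(mode="after")
    def _validate(self):
        taxa = [s.taxon_id for s in self.species]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon in species list")
        if HUMAN_TAXON not in taxa:
            raise ValueError("configuration must include human (taxon 9606)")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source name")
        return self

    def species_for(self, taxon: int) -> SpeciesEntry:
        for s in self.species:
            if s.taxon_id == taxon:
                return s
        raise KeyError(taxon)

    def source_configs(self) -> list[SourceConfig]:
        return [
            SourceConfig(
                name=s.name,
                version_label=s.version_label,
                species_covered=frozenset(s.species),
                file_path=s.file,
            )
            for s in self.sources
        ]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML build config; relative paths resolve against its directory."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    cfg = PipelineConfig.model_validate(data)
    base = path.parent

    def resolve(p: Optional[str]) -> Optional[str]:
        return None if p is None else str((base / p).resolve())

    for sp in cfg.species:
        sp.mod_file = resolve(sp.mod_file)
        sp.ensembl_file = resolve(sp.ensembl_file)
        sp.ncbi_file = resolve(sp.ncbi_file)
    for src in cfg.sources:
        src.file = resolve(src.file)
    cfg.artifacts_dir = resolve(cfg.artifacts_dir)
    return cfg


# ---------------------------------------------------------------------------
# build state


@dataclass
class BuildState:
    """Persisted fingerprints: per input, and per artifact's upstream set."""

    inputs: dict[str, str] = field(default_factory=dict)
    artifacts: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "BuildState":
        path = Path(path)
        if not path.exists():
            return cls()
        data = json.loads(path.read_text())
        return cls(inputs=data.get("inputs", {}), artifacts=data.get("artifacts", {}))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = json.dumps(
            {"inputs": self.inputs, "artifacts": self.artifacts},
            indent=2, sort_keys=True,
        )
        fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".state-")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def fingerprint_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def input_fingerprints(config: PipelineConfig) -> dict[str, str]:
    """Fingerprint every declared input file, keyed by role."""
    prints: dict[str, str] = {}
    for sp in config.species:
        for role, p in (("mod", sp.mod_file), ("ensembl", sp.ensembl_file),
                        ("ncbi", sp.ncbi_file)):
            if p:
                prints[f"gene:{sp.taxon_id}:{role}"] = fingerprint_file(p)
    for src in config.sources:
        prints[f"source:{src.name}"] = fingerprint_file(src.file)
    return prints


def detect_changes(state: BuildState, inputs: dict[str, str]) -> set[str]:
    """Input keys whose fingerprint differs from (or is absent in) state."""
    return {k for k, v in inputs.items() if state.inputs.get(k) != v}


# ---------------------------------------------------------------------------
# planning

Step = tuple[str, int | str]  # ("equivalency", taxon) | ("normalize", src) | ("combine", taxon)


def _propagate(
    taxa_changed: set[int],
    sources_changed: set[str],
    config: PipelineConfig,
    extra_combines: set[int] = frozenset(),
) -> list[Step]:
    """Topologically ordered steps implied by dirty taxa/sources.

    A dirty taxon rebuilds its equivalency table and re-normalizes every
    source covering it, but only species pairs involving that taxon are
    re-combined — a source's normalized rows for other taxa are unchanged,
    so their combines stay valid.  A dirty *source file* re-combines every
    species the source covers, since any of its rows may have changed.
    A dirty human taxon touches every pair.
    """
    renorm = set(sources_changed)
    for src in config.sources:
        if taxa_changed & set(src.species):
            renorm.add(src.name)

    all_targets = {
        t for src in config.sources for t in src.species if t != HUMAN_TAXON
    }
    recombine: set[int] = set(extra_combines)
    if HUMAN_TAXON in taxa_changed:
        recombine |= all_targets
    recombine |= {t for t in taxa_changed if t != HUMAN_TAXON}
    for src in config.sources:
        if src.name in sources_changed:
            recombine |= {t for t in src.species if t != HUMAN_TAXON}

    return (
        [("equivalency", t) for t in sorted(taxa_changed)]
        + [("normalize", s) for s in sorted(renorm)]
        + [("combine", t) for t in sorted(recombine & all_targets)]
    )


def plan_rebuild(changed: set[str], config: PipelineConfig) -> list[Step]:
    """Dependency-correct, topologically ordered build plan for a change set.

    Gene-table changes regenerate the species' equivalency table, then
    every source covering the species is re-normalized, then the species
    pairs actually affected are re-combined.  Source-file changes
    re-normalize that source and re-combine all its species.
    """
    taxa_changed = {
        int(k.split(":")[1]) for k in changed if k.startswith("gene:")
    }
    sources_changed = {k.split(":", 1)[1] for k in changed if k.startswith("source:")}
    return _propagate(taxa_changed, sources_changed, config)


# ---------------------------------------------------------------------------
# artifact persistence

_EQUIV_COLUMNS = ("taxon_id", "mod_id", "ensembl_id", "ncbi_id", "uniprot_ids",
                  "symbol", "name", "locus_type", "location", "status", "provenance")

_NORM_COLUMNS = ("source", "query_taxon", "query_key",
                 "target_taxon", "target_key", "raw_assertion_id")


def _write_equivalency(table: EquivalencyTable, path: Path) -> int:
    rows = sorted(table.rows, key=lambda r: r.composite_key().display())
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EQUIV_COLUMNS)
        for r in rows:
            w.writerow([
                r.taxon_id, r.mod_id or "", r.ensembl_id or "",
                "" if r.ncbi_id is None else r.ncbi_id,
                "|".join(sorted(r.uniprot_ids)), r.symbol, r.name,
                r.locus_type, r.location, r.nomenclature_status, r.provenance,
            ])
    return len(rows)


def _read_equivalency(path: Path, taxon: int) -> EquivalencyTable:
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(GeneRecord(
                taxon_id=int(row["taxon_id"]),
                mod_id=row["mod_id"] or None,
                ensembl_id=row["ensembl_id"] or None,
                ncbi_id=int(row["ncbi_id"]) if row["ncbi_id"] else None,
                uniprot_ids=frozenset(a for a in row["uniprot_ids"].split("|") if a),
                symbol=row["symbol"], name=row["name"],
                locus_type=row["locus_type"], location=row["location"],
                nomenclature_status=row["status"], provenance=row["provenance"],
            ))
    return EquivalencyTable(taxon, records)


def _write_normalized(assertions: list[NormalizedAssertion], path: Path) -> int:
    rows = sorted(assertions, key=lambda a: (
        a.query_taxon, a.target_taxon, a.query_key.display(), a.target_key.display(),
    ))
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_NORM_COLUMNS)
        for a in rows:
            w.writerow([
                a.source, a.query_taxon, a.query_key.display(),
                a.target_taxon, a.target_key.display(), a.raw_assertion_id,
            ])
    return len(rows)


def _read_normalized(path: Path) -> list[NormalizedAssertion]:
    out = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(NormalizedAssertion(
                source=row["source"],
                query_key=CompositeGeneKey.parse(row["query_key"]),
                target_key=CompositeGeneKey.parse(row["target_key"]),
                query_taxon=int(row["query_taxon"]),
                target_taxon=int(row["target_taxon"]),
                raw_assertion_id=row["raw_assertion_id"],
            ))
    return out


class BuildPaths:
    """Artifact file layout under the configured artifacts directory."""

    def __init__(self, artifacts_dir: str | Path):
        self.root = Path(artifacts_dir)

    def equivalency(self, taxon: int) -> Path:
        return self.root / f"equivalency_{taxon}.tsv"

    def normalized(self, source: str) -> Path:
        safe = source.replace("/", "_").replace(" ", "_")
        return self.root / f"normalized_{safe}.tsv"

    def unmapped(self, source: str) -> Path:
        safe = source.replace("/", "_").replace(" ", "_")
        return self.root / f"unmapped_{safe}.tsv"

    def combined(self, taxon: int) -> Path:
        return self.root / f"combined_{taxon}.tsv"

    def state(self) -> Path:
        return self.root / "build_state.json"

    def log(self) -> Path:
        return self.root / "build_log.tsv"


# ---------------------------------------------------------------------------
# execution


@dataclass
class BuildResult:
    state: BuildState
    steps_run: list[tuple[str, str, int]]  # (kind, key, record count)


def _missing_dirty_sets(
    config: PipelineConfig, paths: BuildPaths
) -> tuple[set[int], set[str], set[int]]:
    """Dirty taxa/sources/combines implied by artifacts absent on disk."""
    taxa = {
        sp.taxon_id for sp in config.species
        if not paths.equivalency(sp.taxon_id).exists()
    }
    sources = {
        src.name for src in config.sources
        if not paths.normalized(src.name).exists()
    }
    combined_taxa = {
        t for src in config.sources for t in src.species if t != HUMAN_TAXON
    }
    combines = {t for t in combined_taxa if not paths.combined(t).exists()}
    return taxa, sources, combines


def run(
    config: PipelineConfig,
    state: Optional[BuildState] = None,
    force_full: bool = False,
) -> BuildResult:
    """Execute the (incremental) build and persist artifacts plus new state.

    With no prior state, or ``force_full``, everything is built.  A step
    failure aborts before the new state is persisted, so the previously
    recorded state and its artifacts remain authoritative.
    """
    paths = BuildPaths(config.artifacts_dir)
    paths.root.mkdir(parents=True, exist_ok=True)
    if state is None:
        state = BuildState.load(paths.state())

    prints = input_fingerprints(config)
    if force_full:
        changed = set(prints)
    else:
        changed = detect_changes(state, prints)
    taxa_changed = {int(k.split(":")[1]) for k in changed if k.startswith("gene:")}
    sources_changed = {k.split(":", 1)[1] for k in changed if k.startswith("source:")}
    taxa_missing, sources_missing, combines_missing = _missing_dirty_sets(config, paths)
    steps = _propagate(
        taxa_changed | taxa_missing,
        sources_changed | sources_missing,
        config,
        extra_combines=combines_missing,
    )

    source_cfgs = {s.name: s for s in config.sources}
    equiv_cache: dict[int, EquivalencyTable] = {}

    def get_equivalency(taxon: int) -> EquivalencyTable:
        if taxon not in equiv_cache:
            equiv_cache[taxon] = _read_equivalency(paths.equivalency(taxon), taxon)
        return equiv_cache[taxon]

    steps_run: list[tuple[str, str, int]] = []
    new_state = BuildState(inputs=dict(state.inputs), artifacts=dict(state.artifacts))

    for kind, key in steps:
        if kind == "equivalency":
            sp = config.species_for(int(key))
            def load(p, prov):
                return read_gene_table(p, prov) if p else []
            table = build_equivalency(
                load(sp.mod_file, "mod"),
                load(sp.ensembl_file, "ensembl"),
                load(sp.ncbi_file, "ncbi"),
                sp.taxon_id,
            )
            n = _write_equivalency(table, paths.equivalency(sp.taxon_id))
            equiv_cache[sp.taxon_id] = table
            upstream = {k: prints[k] for k in prints
                        if k.startswith(f"gene:{sp.taxon_id}:")}
            new_state.artifacts[f"equivalency:{sp.taxon_id}"] = {
                "upstream": upstream, "built_at": time.time(),
            }
        elif kind == "normalize":
            src = source_cfgs[str(key)]
            cfg = SourceConfig(
                name=src.name, version_label=src.version_label,
                species_covered=frozenset(src.species), file_path=src.file,
            )
            raws = ingest.read_source_file(cfg)
            tables = {t: get_equivalency(t) for t in src.species}
            normalized, unmapped = ingest.normalize_all(raws, tables)
            deduped = ingest.dedupe_within_source(normalized) if normalized else []
            n = _write_normalized(deduped, paths.normalized(src.name))
            ingest.write_unmapped_report(unmapped, paths.unmapped(src.name))
            new_state.artifacts[f"normalized:{src.name}"] = {
                "upstream": {f"source:{src.name}": prints[f"source:{src.name}"]},
                "built_at": time.time(),
            }
        elif kind == "combine":
            taxon = int(key)
            assertions: list[NormalizedAssertion] = []
            covering = [s for s in config.sources if taxon in s.species]
            for src in covering:
                assertions += [
                    a for a in _read_normalized(paths.normalized(src.name))
                    if taxon in (a.query_taxon, a.target_taxon)
                ]
            metadata = {
                s.name: s.version_label for s in covering
            }
            table = combine(assertions, sources=[
                SourceConfig(s.name, s.version_label, frozenset(s.species), s.file)
                for s in covering
            ], metadata=metadata)
            n = write_snapshot(table, paths.combined(taxon))
            new_state.artifacts[f"combined:{taxon}"] = {
                "upstream": {f"source:{s.name}": prints[f"source:{s.name}"]
                             for s in covering},
                "built_at": time.time(),
            }
        else:  # pragma: no cover
            raise ValueError(f"unknown step kind {kind!r}")
        steps_run.append((kind, str(key), n))
        logger.info("built %s:%s (%d records)", kind, key, n)

    new_state.inputs = prints
    new_state.save(paths.state())
    _append_log(paths.log(), steps_run)
    return BuildResult(state=new_state, steps_run=steps_run)


def _append_log(path: Path, steps_run: list[tuple[str, str, int]]) -> None:
    new = not path.exists()
    with path.open("a", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if new:
            w.writerow(("run_time", "step", "key", "records"))
        stamp = f"{time.time():.3f}"
        for kind, key, n in steps_run:
            w.writerow((stamp, kind, key, n))


# ---------------------------------------------------------------------------
# loading built artifacts for query/export/screen use


def load_registries(config: PipelineConfig) -> dict[int, EquivalencyTable]:
    paths = BuildPaths(config.artifacts_dir)
    return {
        sp.taxon_id: _read_equivalency(paths.equivalency(sp.taxon_id), sp.taxon_id)
        for sp in config.species
        if paths.equivalency(sp.taxon_id).exists()
    }


def load_combined(config: PipelineConfig) -> OrthologTable:
    """One table holding every built species pair."""
    paths = BuildPaths(config.artifacts_dir)
    entries = []
    for sp in config.species:
        if sp.taxon_id == HUMAN_TAXON:
            continue
        p = paths.combined(sp.taxon_id)
        if p.exists():
            entries.extend(read_snapshot(p).entries)
    return OrthologTable(entries)
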