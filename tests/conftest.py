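import random

import pytest

from orthoconsensus import (
    CombinedOrtholog,
    CompositeGeneKey,
    EquivalencyTable,
    GeneRecord,
    Namespace,
    NormalizedAssertion,
    OrthologTable,
    RawAssertion,
    build_equivalency,
    combine,
    normalize_all,
)

HUMAN = 9606
MOUSE = 10090

TWELVE_SOURCES = (
    "Ensembl", "NCBI Gene", "OMA", "PANTHER", "eggNOG", "HomoloGene",
    "Inparanoid", "OrthoDB", "OrthoMCL", "PhylomeDB", "TreeFam", "HGNC",
)


def make_record(taxon=HUMAN, symbol="", **kw):
    defaults = dict(
        taxon_id=taxon,
        symbol=symbol,
        name=f"{symbol} gene" if symbol else "",
        locus_type="protein-coding gene",
        provenance="ensembl",
    )
    defaults.update(kw)
    return GeneRecord(**defaults)


@pytest.fixture
def human_registry():
    """Human table with BRCA1 plus the ABCA1..ABCA13 family."""
    mod_rows = [
        make_record(
            symbol="BRCA1", name="BRCA1 DNA repair associated",
            mod_id="HGNC:1100", ncbi_id=672,
            uniprot_ids=frozenset({"P38398"}),
            nomenclature_status="approved", provenance="mod",
        ),
    ]
    ensembl_rows = [
        make_record(symbol="BRCA1", ensembl_id="ENSG00000012048", ncbi_id=672),
    ]
    for i in range(1, 14):
        mod_rows.append(make_record(
            symbol=f"ABCA{i}", mod_id=f"HGNC:{20 + i}", ncbi_id=100 + i,
            nomenclature_status="approved", provenance="mod",
        ))
        ensembl_rows.append(make_record(
            symbol=f"ABCA{i}", ensembl_id=f"ENSG{90000000000 + i:011d}",
            ncbi_id=100 + i,
        ))
    return build_equivalency(mod_rows, ensembl_rows, [], HUMAN)


@pytest.fixture
def mouse_registry():
    mod_rows = [
        make_record(
            taxon=MOUSE, symbol="Brca1", name="breast cancer 1, early onset",
            mod_id="MGI:104537", ncbi_id=12189,
            nomenclature_status="approved", provenance="mod",
        ),
    ]
    ensembl_rows = [
        make_record(taxon=MOUSE, symbol="Brca1",
                    ensembl_id="ENSMUSG00000017146", ncbi_id=12189),
    ]
    for i in range(1, 14):
        ensembl_rows.append(make_record(
            taxon=MOUSE, symbol=f"Abca{i}",
            ensembl_id=f"ENSMUSG{80000000000 + i:011d}", ncbi_id=200 + i,
        ))
    return build_equivalency(mod_rows, ensembl_rows, [], MOUSE)


@pytest.fixture
def registries(human_registry, mouse_registry):
    return {HUMAN: human_registry, MOUSE: mouse_registry}


@pytest.fixture
def brca1_raw_assertions():
    """Twelve sources asserting human BRCA1 <-> mouse Brca1 in mixed
    namespaces and mixed directions."""
    namespaces = [
        (Namespace.symbol, "BRCA1", Namespace.mod, "MGI:104537"),
        (Namespace.mod, "HGNC:1100", Namespace.ensembl, "ENSMUSG00000017146"),
        (Namespace.ncbi, "672", Namespace.ncbi, "12189"),
        (Namespace.ensembl, "ENSG00000012048", Namespace.symbol, "Brca1"),
        (Namespace.uniprot, "P38398", Namespace.ncbi, "12189"),
    ]
    raws = []
    for i, source in enumerate(TWELVE_SOURCES):
        q_ns, q_id, t_ns, t_id = namespaces[i % len(namespaces)]
        if i % 3 == 2:  # some sources assert mouse->human
            raws.append(RawAssertion(
                source=source, query_taxon=MOUSE, query_namespace=t_ns,
                query_identifier=t_id, target_taxon=HUMAN,
                target_namespace=q_ns, target_identifier=q_id,
                raw_assertion_id=f"{source}-1",
            ))
        else:
            raws.append(RawAssertion(
                source=source, query_taxon=HUMAN, query_namespace=q_ns,
                query_identifier=q_id, target_taxon=MOUSE,
                target_namespace=t_ns, target_identifier=t_id,
                raw_assertion_id=f"{source}-1",
            ))
    return raws


@pytest.fixture
def brca1_table(brca1_raw_assertions, registries):
    normalized, unmapped = normalize_all(brca1_raw_assertions, registries)
    assert not unmapped
    return combine(normalized)


def make_entry(q_ncbi=1, t_ncbi=2, sources=("OMA",), q_taxon=HUMAN, t_taxon=MOUSE,
               q_ens=None, t_ens=None):
    return CombinedOrtholog(
        query_key=CompositeGeneKey(ncbi_id=q_ncbi, ensembl_id=q_ens),
        target_key=CompositeGeneKey(ncbi_id=t_ncbi, ensembl_id=t_ens),
        query_taxon=q_taxon,
        target_taxon=t_taxon,
        supporting_sources=frozenset(sources),
    )


# ---------------------------------------------------------------------------
# independent oracles


def oracle_merge(rows, taxon_id):
    """Brute-force pairwise merge: repeatedly union any two groups sharing a
    mod/ensembl/ncbi identifier, then coalesce field-by-field by priority."""
    priority = {"mod": 0, "ensembl": 1, "ncbi": 2}
    groups = [[(i, r)] for i, r in enumerate(rows)]

    def ids(group):
        out = set()
        for _, r in group:
            if r.mod_id:
                out.add(("mod", r.mod_id.lower()))
            if r.ensembl_id:
                out.add(("ensembl", r.ensembl_id.lower()))
            if r.ncbi_id is not None:
                out.add(("ncbi", str(r.ncbi_id)))
        return out

    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if ids(groups[i]) & ids(groups[j]):
                    groups[i] = groups[i] + groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break

    merged = []
    for group in groups:
        # within an authority the earlier input row wins ties
        ranked = [r for _, r in sorted(group, key=lambda ir: (priority[ir[1].provenance], ir[0]))]

        def first(get, default=None):
            for r in ranked:
                v = get(r)
                if v not in (None, ""):
                    return v
            return default

        uniprot = frozenset().union(*(r.uniprot_ids for r in ranked))
        merged.append(GeneRecord(
            taxon_id=taxon_id,
            symbol=first(lambda r: r.symbol, ""),
            name=first(lambda r: r.name, ""),
            mod_id=first(lambda r: r.mod_id),
            ensembl_id=first(lambda r: r.ensembl_id),
            ncbi_id=first(lambda r: r.ncbi_id),
            uniprot_ids=uniprot,
            locus_type=first(lambda r: r.locus_type, ""),
            location=first(lambda r: r.location, ""),
            nomenclature_status=(
                "approved" if ranked[0].provenance == "mod"
                and any(r.nomenclature_status == "approved" for r in ranked
                        if r.provenance == "mod")
                else "gene"
            ),
            provenance=ranked[0].provenance,
        ))
    # drop groups with no keyable ID, as the builder must
    return [m for m in merged if m.ensembl_id or m.ncbi_id is not None]


def oracle_combine(assertions):
    """Brute-force group-by on canonicalized (human key, other key) pairs."""
    grouped = {}
    for a in assertions:
        if a.query_taxon == HUMAN:
            pair = (a.query_key, a.target_key, a.target_taxon)
        elif a.target_taxon == HUMAN:
            pair = (a.target_key, a.query_key, a.query_taxon)
        else:
            continue
        grouped.setdefault(pair, set()).add(a.source)
    return grouped


def random_normalized_assertions(rng, n, n_sources=6, genes_per_taxon=50,
                                 taxa=(HUMAN, MOUSE, 10116, 9031)):
    """Random human-centric normalized assertions over small key universes."""
    sources = [f"S{i}" for i in range(n_sources)]
    out = []
    for i in range(n):
        other = rng.choice([t for t in taxa if t != HUMAN])
        h = CompositeGeneKey(ncbi_id=rng.randrange(1, genes_per_taxon + 1))
        t = CompositeGeneKey(ncbi_id=other * 100 + rng.randrange(1, genes_per_taxon + 1))
        flip = rng.random() < 0.5
        out.append(NormalizedAssertion(
            source=rng.choice(sources),
            query_key=t if flip else h,
            target_key=h if flip else t,
            query_taxon=other if flip else HUMAN,
            target_taxon=HUMAN if flip else other,
            raw_assertion_id=f"ra{i}",
        ))
    return out
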