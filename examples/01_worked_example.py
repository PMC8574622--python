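"""Aggregate one ortholog pair asserted by twelve resources.

Builds tiny human and mouse identifier registries around BRCA1 / Brca1,
feeds in twelve orthology assertions that each name the genes in a
different identifier namespace (symbol, MOD accession, Ensembl, NCBI,
UniProt), and shows that they all collapse onto a single combined
ortholog keyed by the composite NCBI-Ensembl pairs.
"""

from orthoconsensus import (
    GeneRecord, Namespace, RawAssertion, build_equivalency, combine,
    normalize_all,
)

HUMAN, MOUSE = 9606, 10090

human = build_equivalency(
    [GeneRecord(taxon_id=HUMAN, symbol="BRCA1",
                name="BRCA1 DNA repair associated", mod_id="HGNC:1100",
                ncbi_id=672, uniprot_ids=frozenset({"P38398"}),
                locus_type="protein-coding gene",
                nomenclature_status="approved", provenance="mod")],
    [GeneRecord(taxon_id=HUMAN, symbol="BRCA1", ensembl_id="ENSG00000012048",
                ncbi_id=672, locus_type="protein-coding gene")],
    [], HUMAN)
mouse = build_equivalency(
    [GeneRecord(taxon_id=MOUSE, symbol="Brca1", mod_id="MGI:104537",
                ncbi_id=12189, locus_type="protein-coding gene",
                nomenclature_status="approved", provenance="mod")],
    [GeneRecord(taxon_id=MOUSE, symbol="Brca1",
                ensembl_id="ENSMUSG00000017146", ncbi_id=12189,
                locus_type="protein-coding gene")],
    [], MOUSE)

sources = ["Ensembl", "NCBI Gene", "OMA", "PANTHER", "eggNOG", "HomoloGene",
           "Inparanoid", "OrthoDB", "OrthoMCL", "PhylomeDB", "TreeFam", "HGNC"]
namespaces = [
    (Namespace.symbol, "BRCA1", Namespace.mod, "MGI:104537"),
    (Namespace.mod, "HGNC:1100", Namespace.ensembl, "ENSMUSG00000017146"),
    (Namespace.ncbi, "672", Namespace.ncbi, "12189"),
    (Namespace.ensembl, "ENSG00000012048", Namespace.symbol, "Brca1"),
    (Namespace.uniprot, "P38398", Namespace.ncbi, "12189"),
]
raws = [
    RawAssertion(source=s, query_taxon=HUMAN, query_namespace=q_ns,
                 query_identifier=q, target_taxon=MOUSE, target_namespace=t_ns,
                 target_identifier=t, raw_assertion_id=f"{s}-1")
    for s, (q_ns, q, t_ns, t) in zip(sources, namespaces * 3)
]

normalized, unmapped = normalize_all(raws, {HUMAN: human, MOUSE: mouse})
table = combine(normalized)

entry = table.entries[0]
print(f"combined entries: {len(table)} (twelve assertions, one gene pair)")
print(f"key pair: {entry.query_key} <-> {entry.target_key}")
print(f"support:  {entry.support_count()} resources "
      f"({', '.join(sorted(entry.supporting_sources))})")
# One entry with support 12 means every resource's claim, regardless of the
# namespace it used, resolved to the same composite NCBI-Ensembl key pair.
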