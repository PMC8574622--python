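# orthoconsensus

Consensus aggregation of pairwise orthology predictions across resources,
with cross-authority gene-identifier reconciliation, documented search and
bulk-export semantics, and a high-confidence screen for automated transfer
of gene nomenclature between vertebrate species.

## The problem

Many resources predict orthologous genes — pairs of genes in different
species descended from one gene in their last common ancestor — but they
disagree: each uses its own methodology (BLAST-style alignment, HMMs,
phylogenetic trees), its own species set, and crucially its own identifier
universe (Ensembl gene IDs, NCBI Gene IDs, UniProt accessions, model-organism
database accessions, plain symbols). A biologist asking "what is the mouse
ortholog of human *BRCA1*?" should not have to query a dozen databases and
reconcile a dozen ID schemes by hand.

`orthoconsensus` does three things:

1. **Identifier reconciliation.** For each species it builds an *equivalency
   table* linking the MOD accession, Ensembl gene ID, NCBI Gene ID and
   UniProt accessions of each gene, coalescing disagreements by authority
   priority (MOD > Ensembl > NCBI). Every gene is then named by a
   **composite key** — the pair `<NCBI Gene ID>-<Ensembl gene ID>`, e.g.
   `672-ENSG00000012048` for *BRCA1*. Only one side of the key needs to
   exist, so genes annotated by a single authority still participate and
   fewer assertions are lost.

2. **Consensus aggregation.** Each resource's pairwise assertions are
   normalized onto composite keys and merged: assertions naming the same
   key pair, in either direction, become one *combined ortholog* carrying
   the set of supporting resources. The support count — how many resources
   back the pair — is the reliability proxy; no weighted confidence score
   is computed, deliberately, so users judge the evidence themselves.

3. **The high-confidence naming screen.** For transferring human gene
   nomenclature to other vertebrates, a combined ortholog is *high
   confidence* when it is a one-to-one relationship between protein-coding
   genes supported by at least 3 of the 4 voting resources (Ensembl,
   NCBI Gene, OMA, PANTHER). With all 4 voters and clean curator checks the
   human symbol and name transfer automatically; 3 voters, or a failed
   check, flags the pair for manual curation.

The build pipeline is incremental: inputs are fingerprinted by content
hash, and an edit to one species' nomenclature file regenerates only that
species' equivalency table, the normalizations of sources covering it, and
the affected species pairs — provably converging to the same artifacts as
a from-scratch build.

A seeded synthetic-fixture generator (`orthoconsensus.simulate`) fabricates
gene tables and per-source assertion files with known ground truth, so the
whole stack is testable offline.

## Worked example

```sh
python examples/01_worked_example.py
```

prints

```
combined entries: 1 (twelve assertions, one gene pair)
key pair: 672-ENSG00000012048 <-> 12189-ENSMUSG00000017146
support:  12 resources (Ensembl, HGNC, HomoloGene, Inparanoid, NCBI Gene, OMA, OrthoDB, OrthoMCL, PANTHER, PhylomeDB, TreeFam, eggNOG)
```

Twelve assertions naming human *BRCA1* and mouse *Brca1* through five
different identifier namespaces (symbol, HGNC/MGI accession, Ensembl,
NCBI, UniProt) all resolve to the same composite key pair and collapse to
a single combined ortholog with support 12. The other scripts under
`examples/` walk through simulation + querying (including `_`/`*`
wildcards and case-insensitive search), the 6-/15-column bulk exports, the
nomenclature screen, and the cross-resource concordance profile.

The same functionality is available from a shell:

```sh
orthoconsensus simulate --seed 5 --out world --genes-per-taxon 50
orthoconsensus build --config world/config.yaml
orthoconsensus query --config world/config.yaml --terms "SYM1 SYM2*"
orthoconsensus export --config world/config.yaml --mode 15 --scope all --out all.tsv
orthoconsensus vgnc-screen --config world/config.yaml --target-taxon 10090 --out screen.tsv
```

## Layout

- `src/orthoconsensus/registry.py` — gene records, composite keys, equivalency tables
- `src/orthoconsensus/ingest.py` — assertion files, normalization, within-source dedup
- `src/orthoconsensus/aggregate.py` — combined orthologs, support ordering, source exclusion
- `src/orthoconsensus/query.py` — term splitting, prefix stripping, wildcards, result panels
- `src/orthoconsensus/export.py` — 6-/15-column and all-species bulk TSVs
- `src/orthoconsensus/vgnc.py` — high-confidence screen and nomenclature transfer
- `src/orthoconsensus/pipeline.py` — config, change detection, incremental builds
- `src/orthoconsensus/simulate.py` — synthetic fixtures and concordance reports
- `docs/methods.md` — models, parameters, numerical choices, limitations
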