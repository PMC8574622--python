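# Methods

## Composite gene keys

A gene is identified by the ordered pair of its NCBI Gene ID and Ensembl
stable gene ID, displayed `"<ncbi>-<ensembl>"` with an absent side left
empty (`"-ENSG…"`, `"672-"`). Requiring only one side means a gene model
annotated by a single authority still yields a usable key, so orthology
assertions that can be mapped to only one of the two ID spaces are not
discarded. Parsing splits at the first hyphen; this is unambiguous because
NCBI Gene IDs are purely numeric and Ensembl IDs never begin with a digit.

## Identifier reconciliation

Per species, authority rows (MOD, Ensembl, NCBI) are merged into genes by
union-find: two rows co-refer when they share a MOD, Ensembl or NCBI
identifier. UniProt accessions are accumulated onto the merged gene but
are deliberately **not** used as merge links — protein accessions map
many-to-many onto gene models in real data, and linking on them would
fuse distinct genes. Merged field values coalesce by authority priority
MOD > Ensembl > NCBI, field by field; within one authority the earlier
input row wins ties, making the build deterministic and idempotent.
Nomenclature is flagged `approved` only when a MOD/nomenclature-committee
row supplied it; otherwise it is `gene` (imported from Ensembl or NCBI).

Two policies fill genuine gaps in the documented behaviour:

- **Unkeyable groups** (no Ensembl or NCBI ID anywhere in the merged
  group) are rejected with a logged reason — they cannot form a composite
  key.
- **Post-merge ID conflicts** (two distinct merged genes claiming one
  Ensembl or NCBI ID) keep the ID on the gene from the higher-priority
  authority and strip it from the other, logging both. With merge links on
  those same namespaces this cannot arise from a normal build; the code
  path guards against hand-constructed tables.

Lookups are case-insensitive. Symbol or UniProt identifiers shared by
more than one gene return nothing (and log) rather than an arbitrary
record, so query output is deterministic. MOD accessions are indexed both
with and without their database prefix (`HGNC:1100` and `1100`), because
searches must work either way.

## Normalization and aggregation

Each source file yields directional raw assertions naming endpoints in
any namespace. Normalization resolves both endpoints through the
equivalency tables and attaches the *full* composite keys — both IDs when
the table knows both, even if the source named only one. Unresolved
assertions go to an unmapped report, never silently dropped; per file,
`normalized + unmapped = raw` always holds.

Aggregation canonicalizes direction human-side-first (the tool is
human-centric: non-human queries are answered from the target side of the
stored pairs) and groups by exact key pair: pairs that agree on the NCBI
ID but differ on the Ensembl ID are distinct entries. The support set is
the union of sources asserting the pair in either direction; the sum of
support-set sizes over the table equals the number of deduped,
direction-canonicalized assertions (a conservation law the tests assert).
Result ordering within a target species is by descending support count,
tie-broken by ascending target symbol then target-key display string.
Excluding a source removes entries supported *only* by excluded sources;
surviving entries keep their full supporting set on display.

No weighted confidence score is computed. Support count is shown and used
for ordering, but scoring schemes were deliberately rejected: a high score
manufactured from correlated annotation pipelines invites false
confidence.

## Search semantics

Multi-term input splits on any run of commas, whitespace or newlines.
Wildcards apply to symbol queries: `_` matches exactly one character, `*`
and `%` match **one or more** characters — `ABCA*` matches `ABCA1` but not
`ABCA` itself. This literal one-or-more reading (unlike SQL `%`'s
zero-or-more) follows the documented semantics; the canonical family
example (`ABCA_` → ABCA1..ABCA9, `ABCA*` → ABCA1..ABCA13) is compatible
with either and is asserted in tests. All matching is case-insensitive.
Leading wildcards are accepted: correctness over index-friendliness at
library scale. Defaults when unstated: human query species, all target
species, all sources included.

## Export formats

The 6-column file carries the two composite keys (4 ID columns), the
comma-joined sorted supporting sources, and pipe-joined raw assertion IDs.
The 15-column file adds MOD ID, name, symbol and location for both genes
(7 columns per side, then support). The all-species variants prepend the
ortholog species' taxon ID (7/16 columns) and sort by taxon then human
key, so cutting on the first column reproduces the per-species files
byte-for-byte below the header. The exact column order is fixed by this
package and documented in the headers; byte-stable deterministic output
(sorted rows, sorted source lists, `-` for missing, UTF-8, Unix newlines)
was prioritized over guessing any particular live service's layout.

## High-confidence nomenclature screen

Voters are Ensembl, NCBI Gene, OMA and PANTHER (name-matched
case-insensitively; the set is injectable). The gate is:
one-to-one ∧ both genes `protein-coding gene` ∧ ≥ 3 voters. One-to-one is
recomputed by degree counting **restricted to voter-supported entries**
of the species pair — competition from non-voting, cluster-style resources
does not break it; this interpretation (the gate concerns the voting
resources) is a design choice. Classification: 4 voters with clean extra
checks → `auto_name`; gate passed otherwise → `manual_curation`; gate
failed → `rejected`, with every failed condition listed in `reasons`.
The curators' full transfer-suitability rule set is not public;
`default_extra_checks` is a stand-in (human symbol exists, is
committee-approved, and is not a placeholder "orf"-style symbol) and any
predicate can be injected. Nomenclature transfer refuses human records
whose nomenclature is not committee-approved.

## Incremental builds

Inputs are fingerprinted by SHA-256 of content, not modification time, so
change detection is reproducible. Staleness propagates along the artifact
DAG: a species' gene-table change rebuilds its equivalency table,
re-normalizes every source covering it, and re-combines only pairs
involving that species — a source's normalized rows for *other* species
are unchanged, so their combines stay valid; a changed source file
re-combines all its species; a human-side change touches every pair.
Missing artifacts are rebuilt regardless of fingerprints. The central
contract — the incremental plan converges byte-for-byte to a from-scratch
build — is asserted over randomized edit sequences in the tests. State is
written atomically after all steps succeed, so a failed step leaves the
previous state authoritative. Steps run sequentially; the topological plan
would admit parallel execution but none is attempted.

## Synthetic worlds

The generator plants, per non-human species, a one-to-one ortholog for
each of `genes_per_taxon` human genes, plus a second co-ortholog for a
`dup_rate` fraction (default 0.05, matching the scale of multi-ortholog
calls reported for well-annotated species pairs). Each of `n_sources`
sources (default 12, the size of a human–mouse aggregation; the roster
starts with the four voters) independently recovers each true pair with
probability `concordance` (default 0.9); a non-recovered pair is either
omitted or, with probability 0.5, asserted against a wrong partner —
representing the two real failure modes, missing annotation and outdated
assemblies. Identifier shapes are realistic (`ENSMUSG` + 11 digits,
numeric NCBI IDs, prefixed MOD accessions); `ensembl_only_rate` and
`ncbi_only_rate` (defaults 0.05) plant single-authority genes, and
`mod_coverage` (default 0.9) controls which genes have committee
nomenclature. Everything derives from one `random.Random(seed)` stream, so
fixture files are byte-identical across runs.

With no co-orthologs, the probability a gene's true pair is unanimously
supported is exactly `concordance ** n_sources`; tests and the acceptance
script check the observed fraction against a 99% binomial interval around
that closed form (n = 2000 genes at the default conditions — large enough
for a tight interval, small enough to run in seconds). What the simulator
does **not** emulate: correlated errors between resources sharing input
annotation, cluster-style resources emitting whole ortholog groups,
paralog structure beyond single co-ortholog duplication, and assembly
drift over time. Tests passing on these worlds therefore validate the
aggregation *mechanics* (key reconciliation, merging, ordering,
invalidation), not the biological accuracy of any real resource mix;
headline concordance percentages of live aggregations depend on the
resource versions loaded and are not reproducible from synthetic data.

## Numerical and degenerate-input choices

- Empty term lists, empty tables and unknown identifiers are legal and
  yield empty results, never errors.
- Tie-breaks everywhere are lexicographic on display strings so every
  output file is byte-stable.
- Gene-table rows violating row-level invariants are skipped with a logged
  line number; a malformed header or unknown namespace token fails the
  whole file — a bad row is data, a bad header is a mis-produced file.
- Probabilities in `SimConfig` are validated to [0, 1]; taxa must start
  with human; seeds are plain Python ints.
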