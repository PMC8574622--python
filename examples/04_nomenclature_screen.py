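"""Run the high-confidence screen used for automated nomenclature transfer.

Builds a simulated human-mouse world, classifies every combined ortholog
under the rule (one-to-one, both protein-coding, >= 3 of the 4 voting
resources: Ensembl, NCBI Gene, OMA, PANTHER), and proposes nomenclature
for the auto-name calls.
"""

import tempfile
from pathlib import Path

from orthoconsensus import SimConfig, load_config, simulate, transfer_nomenclature
from orthoconsensus.pipeline import load_combined, load_registries, run
from orthoconsensus.vgnc import screen_species_pair

HUMAN, MOUSE = 9606, 10090

with tempfile.TemporaryDirectory() as tmp:
    truth = simulate(SimConfig(seed=13, genes_per_taxon=60), Path(tmp) / "world")
    config = load_config(truth.config_path)
    run(config)
    table = load_combined(config)
    registries = load_registries(config)

    calls = screen_species_pair(table, registries, MOUSE)
    counts = {}
    for c in calls:
        counts[c.classification] = counts.get(c.classification, 0) + 1
    print(f"screened {len(calls)} combined orthologs:")
    for k in ("auto_name", "manual_curation", "rejected"):
        print(f"  {k}: {counts.get(k, 0)}")

    for c in calls:
        if c.classification != "auto_name":
            continue
        human = registries[HUMAN].lookup_key(c.entry.query_key)
        target = registries[MOUSE].lookup_key(c.entry.target_key)
        symbol, name = transfer_nomenclature(human, target)
        print(f"  propose {symbol!r} / {name!r} for {c.entry.target_key}")
        break
# auto_name calls had all four voters, a clean one-to-one relationship and
# approved transferable human nomenclature; manual_curation calls passed the
# gate with only three voters (or a failed curator check) and would go to a
# human reviewer.
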