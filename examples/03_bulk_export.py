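"""Write the bulk download files and show their shape.

Exports the 6-column pairwise file, the 15-column annotated file, and the
all-species variant with its leading taxon column, then prints the first
data row of each.
"""

import tempfile
from pathlib import Path

from orthoconsensus import ExportSpec, SimConfig, load_config, simulate
from orthoconsensus.export import write_all_species, write_fifteen_column, write_six_column
from orthoconsensus.pipeline import load_combined, load_registries, run

MOUSE = 10090

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    truth = simulate(SimConfig(seed=7, genes_per_taxon=30), tmp / "world")
    config = load_config(truth.config_path)
    run(config)
    table = load_combined(config)
    registries = load_registries(config)

    n6 = write_six_column(
        table, ExportSpec("six_column", "single_species_pair", MOUSE),
        tmp / "pair6.tsv")
    n15 = write_fifteen_column(
        table, registries, ExportSpec("fifteen_column", "single_species_pair", MOUSE),
        tmp / "pair15.tsv")
    nall = write_all_species(
        table, registries, ExportSpec("fifteen_column", "all_species"),
        tmp / "all16.tsv")

    for name, n in (("pair6.tsv", n6), ("pair15.tsv", n15), ("all16.tsv", nall)):
        lines = (tmp / name).read_text().splitlines()
        fields = lines[1].split("\t") if n else []
        print(f"{name}: {n} rows, {len(fields)} fields; first row: {fields[:5]}...")
# '-' cells mark genes one authority never annotated; the leading column of
# the all-species file is the ortholog species' NCBI taxon ID.
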