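"""Library coverage statistics from the bundled worked-number tables.

Reads the transcribed library metadata and hybridization screens, then
prints organellar contamination rates, genome equivalents per library,
the joint Clarke-Carbon representation probability, and the clone count
a 99% library would need.
"""

from pathlib import Path

import pandas as pd

from bes_survey import (
    HybridizationScreen,
    LibraryMetadata,
    clarke_carbon_clones,
    contamination_rate,
    genome_equivalents,
    p_find_combined,
)

DATA = Path(__file__).parent / "data"
GENOME_SIZE = 1.6e9  # haploid genome, bases

screens = pd.read_csv(DATA / "hybridization_screens.tsv", sep="\t")
for row in screens.itertuples():
    rate = contamination_rate(
        HybridizationScreen(row.probe_set, row.positives, row.clones_screened)
    )
    print(f"{row.probe_set:<26} {row.positives:>4} / {row.clones_screened} = {rate}%")

libraries = pd.read_csv(DATA / "library_metadata.tsv", sep="\t")
terms = []
for row in libraries.itertuples():
    meta = LibraryMetadata(
        row.library_id, row.clone_count, row.mean_insert,
        row.empty_fraction, row.organellar_fraction, GENOME_SIZE,
    )
    eq = genome_equivalents(meta)
    print(f"{row.library_id}: {eq:.2f} genome equivalents (~{round(eq)}X)")
    terms.append((row.clone_count, row.mean_insert))

p = p_find_combined(terms, GENOME_SIZE)
print(f"combined probability of recovering a given locus: {100 * p:.5f}%")
print(
    "clones needed for P=0.99 at 144 kb inserts:",
    clarke_carbon_clones(0.99, 144_000, GENOME_SIZE),
)
# The contamination rates are the fraction of screened colonies that
# hybridized to organelle probes; genome equivalents discount empty and
# organellar clones, and the combined probability shows the two
# libraries jointly cover essentially every single-copy locus.
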