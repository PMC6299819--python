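"""Correct species oversampling and summarize profiles per taxon.

Each strain contributes 1/(strains of its species), so the heavily sequenced
species in the corpus do not dominate the taxon-level profile frequencies.
Writes the per-species relative counts and the per-taxon frequencies.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from domarch import profiles as prof
from domarch import weighting

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    df = pd.read_csv(os.path.join(OUT, "strain_states.tsv"), sep="\t")
    states = prof.frame_to_states(df)
    rel = weighting.relative_counts(states)
    rel.to_csv(os.path.join(OUT, "relative_counts.tsv"), sep="\t", index=False)

    meta = prof.read_metadata(
        os.path.join(OUT, "sim", "metadata.tsv")
    ).drop_duplicates("species")
    taxon_map = dict(zip(meta["species"], meta["taxon"]))
    freqs = weighting.taxon_frequencies(rel, taxon_map)
    freqs.to_csv(os.path.join(OUT, "taxon_frequencies.tsv"), sep="\t", index=False)

    biggest = rel.groupby("species")["strain_count"].sum().idxmax()
    shown = rel[rel["species"] == biggest].copy()
    shown["relative_count"] = shown["relative_count"].round(3)
    print(f"most-sampled species ({biggest}):")
    print(shown.to_string(index=False))
    print(f"wrote {rel['species'].nunique()} species x state rows, "
          f"{freqs['taxon'].nunique()} taxa")


if __name__ == "__main__":
    main()
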