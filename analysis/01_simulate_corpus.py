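"""Simulate the desk-scale study corpus.

Generates a 64-species ultrametric species phylogeny, evolves the five-state
CDCP domain profile along it under the equal-rates Markov process, injects
three horizontal domain transfers to produce a perturbed Competence domain
tree (each transfer also copies the donor's profile into the recipient
lineage), expands species into an oversampled strain corpus, and emits the
raw inputs the rest of the analysis consumes (domtblout, BLAST tabular,
metadata TSV, Newick trees, truth JSON).
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from domarch import synth
from domarch.asr import ErModel
from domarch.trees import write_tree

SEED = 11
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sim")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = synth.SimConfig(
        n_leaves=64, root_state="C", profile_noise=0.05,
        species_oversampling={1: 0.90, 5: 0.07, 20: 0.02, 199: 0.01},
        seed=SEED,
    )
    tree = synth.simulate_yule_tree(config.n_leaves, config.birth_rate, SEED)
    truth = synth.simulate_er_states(
        tree, ErModel(mu=config.er_mu), config.root_state, SEED + 1
    )
    truth, domain_tree = synth.inject_hgt(truth, seed=SEED + 2, n_events=3)
    strains = synth.expand_species_to_strains(truth.leaf_states, config, SEED + 3)
    taxon_map = {sp: f"Taxon{1 + i % 6}" for i, sp in enumerate(sorted(truth.leaf_states))}
    dom, blast, meta = synth.generate_hit_tables(strains, taxon_map, config, SEED + 4)

    write_tree(tree, os.path.join(OUT, "species.nwk"))
    write_tree(domain_tree, os.path.join(OUT, "competence.nwk"))
    for name, text in [("hits.domtblout", dom), ("hits.blast.tsv", blast),
                       ("metadata.tsv", meta)]:
        with open(os.path.join(OUT, name), "w") as fh:
            fh.write(text)
    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump(
            {
                "root_state": config.root_state,
                "leaf_states": truth.leaf_states,
                "hgt_events": truth.hgt_events,
                "strain_states": {s.strain_id: s.state for s in strains},
            },
            fh, indent=2, sort_keys=True,
        )
    n_nc = sum(1 for s in strains if s.state == "NC")
    print(f"simulated {len(truth.leaf_states)} species, {len(strains)} strains "
          f"({n_nc} NC), {len(truth.hgt_events)} transfers -> {os.path.relpath(OUT)}")


if __name__ == "__main__":
    main()
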