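import numpy as np
import pytest

from domarch import synth
from domarch.asr import ASR_STATES, ErModel
from domarch.trees import tree_from_string


@pytest.fixture
def cherry():
    """Two-leaf tree (A:1, B:2)."""
    return tree_from_string("(A:1.0,B:2.0);")


def random_small_tree(rng, max_leaves=6, min_len=0.01, max_len=2.0):
    """Random topology (Yule-shaped) with Uniform branch lengths and random
    five-state tip data; used by the oracle-equivalence checks."""
    n = int(rng.integers(2, max_leaves + 1))
    tree = synth.simulate_yule_tree(n, 1.0, seed=int(rng.integers(2**31)))
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = float(rng.uniform(min_len, max_len))
    leaf_states = {
        lf.taxon.label: ASR_STATES[rng.integers(len(ASR_STATES))]
        for lf in tree.leaf_node_iter()
    }
    mu = float(rng.uniform(0.05, 1.5))
    return tree, leaf_states, mu
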