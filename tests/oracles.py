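"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths under test: the transition kernel
comes from a generic matrix exponential, the likelihood and posteriors from
exhaustive enumeration over all joint ancestral-state assignments, and
patristic distances from the root-depth formula d(a,b) = depth(a) + depth(b)
- 2 depth(LCA).
"""

from __future__ import annotations

from itertools import product
from typing import Dict, Mapping, Tuple

import dendropy
import numpy as np
from scipy.linalg import expm

from domarch.asr import ASR_STATES


def er_rate_matrix(k: int, mu: float) -> np.ndarray:
    q = np.full((k, k), mu)
    np.fill_diagonal(q, -(k - 1) * mu)
    return q


def expm_transition(k: int, mu: float, t: float) -> np.ndarray:
    return expm(er_rate_matrix(k, mu) * t)


def enum_loglik_posteriors(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str],
    mu: float,
    k: int = 5,
) -> Tuple[float, Dict[dendropy.Node, np.ndarray]]:
    """Brute-force likelihood and marginal posteriors.

    Sums prior x product of edge transition probabilities over all k^(number
    of internal nodes) joint assignments; posteriors are the per-node
    conditional sums. Only feasible for tiny trees.
    """
    sidx = {s: i for i, s in enumerate(ASR_STATES[:k])}
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    idx = {n: i for i, n in enumerate(internal)}
    P = {
        n: expm_transition(k, mu, float(n.edge.length or 0.0))
        for n in nodes
        if n.parent_node is not None
    }
    total = 0.0
    post = np.zeros((len(internal), k))
    for assign in product(range(k), repeat=len(internal)):
        p = 1.0 / k  # uniform root prior
        for n in nodes:
            if n.parent_node is None:
                continue
            parent_state = assign[idx[n.parent_node]]
            if n.is_leaf():
                child_state = sidx[leaf_states[n.taxon.label]]
            else:
                child_state = assign[idx[n]]
            p *= P[n][parent_state, child_state]
            if p == 0.0:
                break
        else:
            total += p
            for n in internal:
                post[idx[n], assign[idx[n]]] += p
    if total <= 0.0:
        return float("-inf"), {}
    return float(np.log(total)), {n: post[idx[n]] / total for n in internal}


def rootpath_cophenetic(tree: dendropy.Tree) -> Tuple[list, np.ndarray]:
    """Patristic distances via depths and explicit LCA search."""
    depths: Dict[dendropy.Node, float] = {}
    ancestors: Dict[dendropy.Node, list] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
            ancestors[node] = [node]
        else:
            depths[node] = depths[node.parent_node] + float(node.edge.length or 0.0)
            ancestors[node] = ancestors[node.parent_node] + [node]
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = set(ancestors[leaves[i]])
            lca = next(a for a in reversed(ancestors[leaves[j]]) if a in anc_i)
            d[i, j] = d[j, i] = (
                depths[leaves[i]] + depths[leaves[j]] - 2.0 * depths[lca]
            )
    return labels, d
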