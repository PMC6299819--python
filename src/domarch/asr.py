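"""Five-state equal-rates Markov ancestral-state reconstruction.

The model is the k-state Mk/ER continuous-time Markov chain: every ordered
pair of distinct states exchanges at the same rate mu, so the generator is
``Q = mu * (J - k I)`` (J the all-ones matrix) and the transition kernel has
the Jukes–Cantor-style closed form

    P_ii(t) = 1/k + (1 - 1/k) exp(-k mu t)
    P_ij(t) = 1/k - (1/k)     exp(-k mu t),   i != j.

Tip states over a rooted, branch-length-bearing species phylogeny enter
Felsenstein's pruning algorithm (post-order conditional likelihood vectors
with per-node rescaling); the single rate is fitted by bounded scalar
maximum likelihood; and true marginal posterior state probabilities at every
internal node come from the up–down (outside) pass. The root prior is uniform
over the k states.

The five-state vocabulary is (NC, C, DC, CL, DCL); strains whose protein
carries extra domains (OTHER) are reduced to the core state implied by their
DUF4131/Lactamase_B content before reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .profiles import StrainState

__all__ = [
    "ASR_STATES",
    "ErModel",
    "AsrFit",
    "transition_matrix",
    "pruning_loglik",
    "fit_er_rate",
    "marginal_posteriors",
    "asr_leaf_states",
    "posterior_table",
    "annotate_map_states",
]

#: Fixed state order of the five-state reconstruction.
ASR_STATES = ("NC", "C", "DC", "CL", "DCL")
_STATE_INDEX = {s: i for i, s in enumerate(ASR_STATES)}


@dataclass(frozen=True)
class ErModel:
    """Equal-rates k-state CTMC with a single free rate ``mu``."""

    mu: float
    k: int = 5
    state_order: Tuple[str, ...] = ASR_STATES

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if len(self.state_order) != self.k:
            raise ValueError("state_order length != k")

    def rate_matrix(self) -> np.ndarray:
        q = np.full((self.k, self.k), self.mu)
        np.fill_diagonal(q, -(self.k - 1) * self.mu)
        return q


@dataclass
class AsrFit:
    """Fitted rate, log-likelihood, and per-internal-node posteriors."""

    mu_hat: float
    loglik: float
    posteriors: "Dict[dendropy.Node, np.ndarray]" = field(default_factory=dict)
    leaf_states: Dict[str, str] = field(default_factory=dict)
    rate_at_bound: bool = False
    state_order: Tuple[str, ...] = ASR_STATES


def transition_matrix(model: ErModel, t: float) -> np.ndarray:
    """Closed-form ER transition kernel P(t); rows sum to 1."""
    if t < 0:
        raise ValueError("negative branch length")
    k = model.k
    e = math.exp(-k * model.mu * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, 1.0 / k + (1.0 - 1.0 / k) * e)
    return p


# ---------------------------------------------------------------------------
# tree indexing (built once per tree; reused across rate evaluations)


class _TreeIndex:
    """Flat post-order arrays over a dendropy tree for fast pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes: List[dendropy.Node] = list(tree.postorder_node_iter())
        self.index = {node: i for i, node in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[n.parent_node] if n.parent_node else -1 for n in self.nodes]
        )
        self.edge_length = np.array(
            [float(n.edge.length or 0.0) for n in self.nodes]
        )
        self.children: List[List[int]] = [
            [self.index[c] for c in n.child_nodes()] for n in self.nodes
        ]
        self.is_leaf = np.array([n.is_leaf() for n in self.nodes])
        self.leaf_label = [
            n.taxon.label if n.is_leaf() else None for n in self.nodes
        ]
        self.root = len(self.nodes) - 1


def _leaf_vectors(idx: _TreeIndex, leaf_states: Mapping[str, str], k: int) -> np.ndarray:
    vec = np.zeros((len(idx.nodes), k))
    for i, label in enumerate(idx.leaf_label):
        if label is None:
            continue
        if label not in leaf_states:
            raise KeyError(f"leaf {label!r} has no state")
        state = leaf_states[label]
        if state not in _STATE_INDEX:
            raise ValueError(f"unknown state {state!r} at leaf {label!r}")
        vec[i, _STATE_INDEX[state]] = 1.0
    return vec


def _postorder_partials(
    idx: _TreeIndex, leaf_vec: np.ndarray, model: ErModel
) -> Tuple[np.ndarray, float, List[Optional[np.ndarray]]]:
    """Scaled conditional likelihoods and the accumulated log scale.

    Also returns, per node, the parent-side message P(t_child) @ partial_child
    used again by the outside pass. A log scale of -inf signals impossible
    data (zero likelihood).
    """
    k = model.k
    n = len(idx.nodes)
    partial = np.empty((n, k))
    messages: List[Optional[np.ndarray]] = [None] * n
    logscale = 0.0
    for i in range(n):
        if idx.is_leaf[i]:
            v = leaf_vec[i].copy()
        else:
            v = np.ones(k)
            for c in idx.children[i]:
                p = transition_matrix(model, idx.edge_length[c])
                msg = p @ partial[c]
                messages[c] = msg
                v *= msg
        m = v.max()
        if m <= 0.0:
            return partial, -math.inf, messages
        if m < 1e-280:  # rescale to dodge underflow on deep trees
            v = v / m
            logscale += math.log(m)
        partial[i] = v
    # final root rescale so downstream consumers see O(1) numbers
    m = partial[idx.root].max()
    partial[idx.root] /= m
    logscale += math.log(m)
    return partial, logscale, messages


def pruning_loglik(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str],
    model: ErModel,
    _idx: Optional[_TreeIndex] = None,
) -> float:
    """Felsenstein-pruning log-likelihood of the tip states.

    Uses a uniform root prior 1/k. Returns ``-inf`` for data of probability
    zero (e.g. conflicting states across zero-length branches).
    """
    idx = _idx or _TreeIndex(tree)
    leaf_vec = _leaf_vectors(idx, leaf_states, model.k)
    partial, logscale, _ = _postorder_partials(idx, leaf_vec, model)
    if not math.isfinite(logscale):
        return -math.inf
    total = partial[idx.root].sum() / model.k
    if total <= 0.0:
        return -math.inf
    return logscale + math.log(total)


def fit_er_rate(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str],
    bounds: Tuple[float, float] = (1e-8, 100.0),
    k: int = 5,
) -> AsrFit:
    """Maximum-likelihood ER rate by bounded derivative-free search.

    A coarse log-spaced grid (50 points) locates the basin first, then Brent's
    bounded method refines to an absolute rate tolerance of 1e-8; the grid
    guards against the flat likelihood surfaces that arise with nearly
    uninformative data. If the tips are monomorphic the rate is unidentifiable
    (likelihood monotone decreasing in mu) and the lower bound is returned
    with ``rate_at_bound`` set.
    """
    lo, hi = bounds
    idx = _TreeIndex(tree)
    observed = {leaf_states[lab] for lab in idx.leaf_label if lab is not None}

    def negloglik(mu: float) -> float:
        return -pruning_loglik(tree, leaf_states, ErModel(mu=mu, k=k), _idx=idx)

    if len(observed) < 2:
        return AsrFit(
            mu_hat=lo,
            loglik=-negloglik(lo),
            leaf_states=dict(leaf_states),
            rate_at_bound=True,
        )

    grid = np.geomspace(lo, hi, 50)
    grid_vals = np.array([negloglik(m) for m in grid])
    best = int(np.argmin(grid_vals))
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        negloglik, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-8}
    )
    mu_hat, val = float(res.x), float(res.fun)
    if grid_vals[best] < val:
        mu_hat, val = float(grid[best]), float(grid_vals[best])
    at_bound = mu_hat <= lo * (1 + 1e-6) or mu_hat >= hi * (1 - 1e-6)
    return AsrFit(
        mu_hat=mu_hat,
        loglik=-val,
        leaf_states=dict(leaf_states),
        rate_at_bound=at_bound,
    )


def marginal_posteriors(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str],
    model: ErModel,
) -> Dict[dendropy.Node, np.ndarray]:
    """True marginal posterior state distributions at every internal node.

    Up–down algorithm: the post-order (inside) pass gives the likelihood of
    the data below each node; the pre-order (outside) pass gives the
    likelihood of everything else conditional on the node's state; their
    product, normalized per node, is the marginal posterior. The root
    posterior is proportional to prior x root conditional likelihood.
    """
    idx = _TreeIndex(tree)
    k = model.k
    leaf_vec = _leaf_vectors(idx, leaf_states, k)
    partial, logscale, messages = _postorder_partials(idx, leaf_vec, model)
    if not math.isfinite(logscale) or partial[idx.root].sum() <= 0.0:
        raise ValueError("tip data have zero likelihood under the model")

    outside = np.empty((len(idx.nodes), k))
    outside[idx.root] = 1.0 / k  # uniform root prior
    posteriors: Dict[dendropy.Node, np.ndarray] = {}
    for i in range(len(idx.nodes) - 1, -1, -1):
        node = idx.nodes[i]
        if not idx.is_leaf[i]:
            post = outside[i] * partial[i]
            posteriors[node] = post / post.sum()
            children = idx.children[i]
            for c in children:
                sib = outside[i].copy()
                for other in children:
                    if other != c:
                        sib *= messages[other]
                p = transition_matrix(model, idx.edge_length[c])
                out = p.T @ sib
                m = out.max()
                outside[c] = out / m if m > 0 else out
    return posteriors


# ---------------------------------------------------------------------------
# glue: strain states -> five-state leaf data; posterior reporting


def asr_leaf_states(states: Sequence[StrainState]) -> Dict[str, str]:
    """Map strain states onto the five reconstruction states.

    OTHER strains reduce to the core state implied by the D/L content of
    their classifying CDCP (a protein with extra domains still carries a
    Competence domain, so it is at least C).
    """
    table = {
        (False, False): "C",
        (True, False): "DC",
        (False, True): "CL",
        (True, True): "DCL",
    }
    out: Dict[str, str] = {}
    for s in states:
        if s.state == "OTHER":
            out[s.strain_id] = table[(s.has_duf4131, s.has_lactamase_b)]
        else:
            out[s.strain_id] = s.state
    return out


def _node_label(node: dendropy.Node, fallback: str) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return fallback


def posterior_table(
    tree: dendropy.Tree, posteriors: Mapping[dendropy.Node, np.ndarray]
) -> pd.DataFrame:
    """Posteriors as a DataFrame, one row per internal node (pre-order),
    unlabeled nodes named ``node<i>``."""
    rows = []
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        post = posteriors[node]
        row = {"node": _node_label(node, f"node{i}")}
        row.update({state: float(p) for state, p in zip(ASR_STATES, post)})
        row["map_state"] = ASR_STATES[int(np.argmax(post))]
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_map_states(
    tree: dendropy.Tree, posteriors: Mapping[dendropy.Node, np.ndarray]
) -> dendropy.Tree:
    """Attach the MAP state to each internal node label (``label|STATE``)."""
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        map_state = ASR_STATES[int(np.argmax(posteriors[node]))]
        base = _node_label(node, f"node{i}")
        node.label = f"{base}|{map_state}"
    return tree
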