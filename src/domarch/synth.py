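"""Synthetic corpora with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised at desk scale without any
download: ultrametric pure-birth (Yule) species trees; five-state domain
profiles evolving along them under the equal-rates Markov process; per-species
strain multiplicity with occasional deviant profiles (emulating e.g. the
9/13/177 split observed among *E. coli* strains); domain trees that are copies
of the species tree perturbed by injected horizontal transfer events; and
HMMER/BLAST-style hit tables whose e-values and coverages deliberately
straddle the filtering thresholds.

All randomness flows through a single integer seed per call, via
``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .asr import ASR_STATES, ErModel
from .profiles import (
    COMPETENCE,
    DUF4131,
    LACTAMASE_B,
    StrainState,
)
from .trees import node_depths, tree_to_string

__all__ = [
    "DECOY_DOMAINS",
    "MODEL_LENGTHS",
    "SimConfig",
    "SimTruth",
    "simulate_yule_tree",
    "scale_branch_lengths",
    "scale_to_height",
    "jitter_branch_lengths",
    "simulate_er_states",
    "inject_hgt",
    "expand_species_to_strains",
    "generate_hit_tables",
    "ecoli_example_states",
    "census_corpus",
]

#: Low-frequency domains observed to co-occur with Competence; any of these in
#: a protein makes its profile OTHER.
DECOY_DOMAINS = ("PF12706", "PF13483", "PF12695", "PF12697", "PF10531")

#: Profile-HMM model lengths used when emitting synthetic domtblout rows.
MODEL_LENGTHS: Dict[str, int] = {
    COMPETENCE: 241,
    DUF4131: 219,
    LACTAMASE_B: 228,
    "PF12706": 160,
    "PF13483": 150,
    "PF12695": 130,
    "PF12697": 140,
    "PF10531": 60,
}

_DOMAIN_NAMES = {
    COMPETENCE: "Competence",
    DUF4131: "DUF4131",
    LACTAMASE_B: "Lactamase_B",
    "PF12706": "Lactamase_B_2",
    "PF13483": "Lactamase_B_3",
    "PF12695": "Abhydrolase_5",
    "PF12697": "Abhydrolase_6",
    "PF10531": "SLBB",
}

_STATE_DOMAINS = {
    "C": (COMPETENCE,),
    "DC": (DUF4131, COMPETENCE),
    "CL": (COMPETENCE, LACTAMASE_B),
    "DCL": (DUF4131, COMPETENCE, LACTAMASE_B),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic corpus.

    ``species_oversampling`` maps a strain count to the probability that a
    species has that many sequenced strains; ``profile_noise`` is the
    per-strain probability of deviating from its species' profile;
    ``rescue_prob`` is the probability that an NC strain still carries a
    genomic Competence fragment (the study observed 409 of 640).
    """

    n_leaves: int = 64
    birth_rate: float = 1.0
    er_mu: float = 0.05
    root_state: str = "C"
    hgt_rate: float = 0.0
    species_oversampling: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.90, 5: 0.07, 20: 0.02, 199: 0.01}
    )
    profile_noise: float = 0.05
    straddle_fraction: float = 0.10
    rescue_prob: float = 0.64
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.species_oversampling.values()) < 0:
            raise ValueError("oversampling probabilities must be >= 0")
        if not math.isclose(sum(self.species_oversampling.values()), 1.0):
            raise ValueError("oversampling probabilities must sum to 1")
        for name in ("er_mu", "hgt_rate", "birth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("profile_noise", "straddle_fraction", "rescue_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    tree: dendropy.Tree
    node_states: Dict[dendropy.Node, str]
    events: List[Tuple[str, float, str]]  # (node label below edge, time, new state)
    leaf_states: Dict[str, str] = field(default_factory=dict)
    hgt_events: List[dict] = field(default_factory=list)
    model: Optional[ErModel] = None


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(
    n_leaves: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with exactly *n_leaves* tips.

    Starting from two lineages at the root, each epoch with k lineages lasts
    Exp(k * birth_rate) after which a uniformly chosen lineage splits; the
    final epoch (n lineages) also lasts Exp(n * birth_rate). Leaf labels are
    ``S0001..``; internal nodes are labeled ``N1..`` in creation order.
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.label = "N1"
    birth_time: Dict[dendropy.Node, float] = {}
    active: List[dendropy.Node] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        birth_time[child] = 0.0
        active.append(child)
    t = 0.0
    n_internal = 1
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth_time[node]
        n_internal += 1
        node.label = f"N{n_internal}"
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_leaves))
    for i, node in enumerate(
        sorted(active, key=lambda nd: birth_time[nd]), start=1
    ):
        node.edge.length = t - birth_time[node]
        node.taxon = taxa.new_taxon(label=f"S{i:04d}")
    tree.seed_node.edge.length = None
    return tree


def scale_branch_lengths(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    """Return a copy with every branch length multiplied by *factor*."""
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= factor
    return out


def scale_to_height(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    """Rescale so the maximum root-to-tip depth equals *height*."""
    current = max(node_depths(tree).values())
    if current <= 0:
        raise ValueError("tree has zero height")
    return scale_branch_lengths(tree, height / current)


def jitter_branch_lengths(
    tree: dendropy.Tree, sigma: float, seed: int = 0
) -> dendropy.Tree:
    """Multiply each branch by LogNormal(0, sigma) to emulate rate variation
    (the real species tree is not ultrametric)."""
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= float(rng.lognormal(0.0, sigma))
    return out


# ---------------------------------------------------------------------------
# trait evolution


def simulate_er_states(
    tree: dendropy.Tree, model: ErModel, root_state: str, seed: int = 0
) -> SimTruth:
    """Evolve a discrete state along the tree under the ER process.

    Gillespie simulation per branch: waiting times Exp((k-1) * mu), each event
    jumping to a uniformly chosen different state. The full event history is
    recorded as (label of the node below the branch, absolute time, new
    state). ``mu = 0`` is allowed: every node inherits the root state.
    """
    if root_state not in model.state_order:
        raise ValueError(f"root_state {root_state!r} not in state order")
    rng = np.random.default_rng(seed)
    depths = node_depths(tree)
    states: Dict[dendropy.Node, str] = {tree.seed_node: root_state}
    events: List[Tuple[str, float, str]] = []
    order = list(model.state_order)
    total_rate = (model.k - 1) * model.mu
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state = states[node.parent_node]
        length = node.edge.length or 0.0
        if total_rate > 0:
            t = 0.0
            while True:
                t += rng.exponential(1.0 / total_rate)
                if t > length:
                    break
                others = [s for s in order if s != state]
                state = others[rng.integers(len(others))]
                label = node.taxon.label if node.is_leaf() else node.label
                events.append((label, depths[node.parent_node] + t, state))
        states[node] = state
    leaf_states = {
        leaf.taxon.label: states[leaf] for leaf in tree.leaf_node_iter()
    }
    return SimTruth(
        tree=tree, node_states=states, events=events, leaf_states=leaf_states,
        model=model,
    )


# ---------------------------------------------------------------------------
# horizontal transfer


def _node_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        key = node.taxon.label if node.taxon is not None else node.label
        if key == label:
            return node
    raise KeyError(f"no node labeled {label!r}")


def _label_of(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _apply_transfer(
    tree: dendropy.Tree, recipient_label: str, donor_label: str, tau: float
) -> bool:
    """Regraft the recipient subtree as sister to the donor lineage at time
    *tau* on an ultrametric tree; returns False if a previous regraft made
    the event inapplicable."""
    depths = node_depths(tree)
    r = _node_by_label(tree, recipient_label)
    pr = r.parent_node
    if pr is None or depths[pr] >= tau or depths[r] < tau:
        return False
    d = _node_by_label(tree, donor_label)
    if depths[d] < tau:
        return False
    while d.parent_node is not None and depths[d.parent_node] >= tau:
        d = d.parent_node
    if d.parent_node is None:
        return False
    anc = d
    while anc is not None:  # donor lineage must not sit inside the moved clade
        if anc is r:
            return False
        anc = anc.parent_node
    # split the donor edge at tau first (so recipient detachment cannot
    # orphan the donor when the two are siblings)
    pd = d.parent_node
    x = dendropy.Node()
    pd.remove_child(d)
    pd.add_child(x)
    x.edge.length = tau - depths[pd]
    d.edge.length = depths[d] - tau
    x.add_child(d)
    # move the recipient under the new node and suppress its unary ex-parent
    pr.remove_child(r)
    x.add_child(r)
    r.edge.length = depths[r] - tau
    if pr.num_child_nodes() == 1:
        only = pr.child_nodes()[0]
        gp = pr.parent_node
        pr.remove_child(only)
        if gp is None:
            only.edge.length = None
            tree.seed_node = only
        else:
            only.edge.length = (only.edge.length or 0.0) + (pr.edge.length or 0.0)
            gp.remove_child(pr)
            gp.add_child(only)
    return True


def _donor_state_at(truth: SimTruth, donor_label: str, tau: float) -> str:
    """Profile state of the donor lineage at absolute time *tau*."""
    donor = _node_by_label(truth.tree, donor_label)
    state = truth.node_states[donor.parent_node]
    for label, time, new_state in sorted(
        (e for e in truth.events if e[0] == donor_label and e[1] <= tau),
        key=lambda e: e[1],
    ):
        state = new_state
    return state


def _copy_state_into_recipient(
    truth: SimTruth, recipient_label: str, tau: float, donor_state: str,
    rng: np.random.Generator,
) -> None:
    """Replace the recipient lineage's state at *tau* by the donor's and
    re-evolve the recipient subtree from there under the same ER process."""
    model = truth.model
    depths = node_depths(truth.tree)
    r = _node_by_label(truth.tree, recipient_label)
    sub_labels = {_label_of(n) for n in r.preorder_iter()}
    # the recipient's own history before tau stands; everything after is
    # superseded by the transferred state
    truth.events = [
        e for e in truth.events
        if e[0] not in sub_labels or (e[0] == recipient_label and e[1] <= tau)
    ]
    order = list(model.state_order)
    total_rate = (model.k - 1) * model.mu

    def evolve(state: str, label: str, t_start: float, t_end: float) -> str:
        if total_rate <= 0:
            return state
        t = t_start
        while True:
            t += rng.exponential(1.0 / total_rate)
            if t > t_end:
                return state
            others = [s for s in order if s != state]
            state = others[rng.integers(len(others))]
            truth.events.append((label, t, state))

    truth.node_states[r] = evolve(donor_state, recipient_label, tau, depths[r])
    for node in r.preorder_iter():
        if node is r:
            continue
        state = evolve(
            truth.node_states[node.parent_node], _label_of(node),
            depths[node.parent_node], depths[node],
        )
        truth.node_states[node] = state
        if node.is_leaf():
            truth.leaf_states[node.taxon.label] = state
    if r.is_leaf():
        truth.leaf_states[r.taxon.label] = truth.node_states[r]


def inject_hgt(
    truth: SimTruth,
    hgt_rate: float = 0.0,
    seed: int = 0,
    n_events: Optional[int] = None,
) -> Tuple[SimTruth, dendropy.Tree]:
    """Place transfer events on the species tree and emit the perturbed
    domain tree.

    Events form a Poisson process of intensity *hgt_rate* per unit branch
    length (or exactly *n_events* events placed proportional to branch
    length). At each event a contemporaneous donor lineage is drawn
    uniformly, the recipient lineage's profile state is replaced by the
    donor's state at the event time (the recipient subtree re-evolves from
    it), and in the returned domain tree the recipient subtree is regrafted
    as sister to the donor at the event time, preserving the tip count.
    Events are recorded on ``truth.hgt_events`` with their recipient and
    donor tip sets.
    """
    if hgt_rate < 0:
        raise ValueError("hgt_rate must be >= 0")
    rng = np.random.default_rng(seed)
    tree = truth.tree
    depths = node_depths(tree)
    edges = [
        (node, depths[node.parent_node], float(node.edge.length or 0.0))
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and (node.edge.length or 0.0) > 0
    ]
    total_len = sum(e[2] for e in edges)
    exact = n_events is not None
    if n_events is None:
        n_events = int(rng.poisson(hgt_rate * total_len))
    weights = np.array([e[2] for e in edges]) / total_len

    def draw(count: int) -> List[dict]:
        out = []
        for _ in range(count):
            node, pdepth, length = edges[rng.choice(len(edges), p=weights)]
            tau = pdepth + rng.uniform(0.0, length)
            donors = [
                e[0]
                for e in edges
                if e[0] is not node and e[1] < tau <= e[1] + e[2]
            ]
            if not donors:
                continue
            donor = donors[rng.integers(len(donors))]
            out.append(
                {
                    "recipient": _label_of(node),
                    "donor": _label_of(donor),
                    "time": float(tau),
                    "recipient_tips": sorted(
                        lf.taxon.label for lf in node.leaf_iter()
                    ),
                    "donor_tips": sorted(
                        lf.taxon.label for lf in donor.leaf_iter()
                    ),
                }
            )
        return out

    domain_tree = tree.clone(depth=1)
    applied: List[dict] = []
    batches = 0
    pending = sorted(draw(n_events), key=lambda e: e["time"])
    while True:
        for ev in pending:
            if len(applied) >= n_events:
                break
            if _apply_transfer(
                domain_tree, ev["recipient"], ev["donor"], ev["time"]
            ):
                donor_state = _donor_state_at(truth, ev["donor"], ev["time"])
                ev["donor_state"] = donor_state
                if truth.model is not None:
                    _copy_state_into_recipient(
                        truth, ev["recipient"], ev["time"], donor_state, rng
                    )
                applied.append(ev)
            elif not exact:
                n_events -= 1  # Poisson mode: a skipped event stays skipped
        if len(applied) >= n_events or not exact or batches >= 50:
            break
        # exact mode: redraw events that turned out to be inapplicable
        batches += 1
        pending = sorted(draw(n_events - len(applied)), key=lambda e: e["time"])
    truth.hgt_events = applied
    return truth, domain_tree


# ---------------------------------------------------------------------------
# strains and hit tables


def expand_species_to_strains(
    leaf_states: Mapping[str, str], config: SimConfig, seed: int = 0
) -> List[StrainState]:
    """Expand one-state-per-species truth into a multi-strain corpus.

    Each species draws its strain count from ``config.species_oversampling``;
    each strain keeps the species state except with probability
    ``config.profile_noise``, in which case it draws a different state
    uniformly (including OTHER). NC strains carry a genomic fragment with
    probability ``config.rescue_prob``.
    """
    rng = np.random.default_rng(seed)
    counts = sorted(config.species_oversampling)
    probs = np.array([config.species_oversampling[c] for c in counts])
    six_states = list(ASR_STATES) + ["OTHER"]
    strains: List[StrainState] = []
    for species in sorted(leaf_states):
        n_strains = counts[rng.choice(len(counts), p=probs)]
        for j in range(1, n_strains + 1):
            state = leaf_states[species]
            if rng.random() < config.profile_noise:
                others = [s for s in six_states if s != state]
                state = others[rng.integers(len(others))]
            if state == "OTHER":
                has_d, has_l = bool(rng.integers(2)), bool(rng.integers(2))
            else:
                has_d = "D" in state and state != "NC"
                has_l = "L" in state
            strains.append(
                StrainState(
                    strain_id=f"{species}.{j}",
                    species=species,
                    state=state,
                    cdcp_count=0 if state == "NC" else 1,
                    genomic_fragment=(
                        state == "NC" and rng.random() < config.rescue_prob
                    ),
                    has_duf4131=has_d if state != "NC" else False,
                    has_lactamase_b=has_l if state != "NC" else False,
                )
            )
    return strains


def _domtbl_row(
    protein: str,
    protein_len: int,
    accession: str,
    evalue: float,
    model_cov: float,
    env_start: int,
    rng: np.random.Generator,
) -> str:
    """One domtblout line (hmmsearch orientation: query = HMM)."""
    qlen = MODEL_LENGTHS[accession]
    # ceil for passing coverages (span/qlen >= cov), floor for failing ones,
    # so integer spans land on the intended side of the 0.70 threshold
    if model_cov >= 0.70:
        span = min(qlen, int(math.ceil(model_cov * qlen)))
    else:
        span = max(1, int(math.floor(model_cov * qlen)))
    hmm_from = 1 + int(rng.integers(0, qlen - span + 1))
    hmm_to = hmm_from + span - 1
    env_end = env_start + span - 1
    score = float(-10.0 * math.log10(max(evalue, 1e-300)))
    # 6 significant digits so threshold-straddling e-values (1.0001e-5) do
    # not round back onto the boundary
    cols = [
        protein, "-", str(protein_len),
        _DOMAIN_NAMES[accession], f"{accession}.10", str(qlen),
        f"{evalue:.6g}", f"{score:.1f}", "0.1", "1", "1",
        f"{evalue:.6g}", f"{evalue:.6g}", f"{score:.1f}", "0.1",
        str(hmm_from), str(hmm_to), str(env_start), str(env_end),
        str(env_start), str(env_end), "0.95", "-",
    ]
    return " ".join(cols)


def _protein_rows(
    strain_id: str,
    protein: str,
    domains: Sequence[str],
    rng: np.random.Generator,
    straddle_fraction: float,
    length: Optional[int] = None,
) -> Tuple[List[str], int]:
    """domtblout rows realizing one protein's domain content, plus optional
    threshold-straddling decoys (which the filter must remove)."""
    n = len(domains)
    plen = length if length is not None else 300 + 230 * n
    rows = []
    pos = 5
    for acc in domains:
        evalue = float(10 ** rng.uniform(-30, math.log10(1e-5)))
        cov = float(rng.uniform(0.70, 1.0))
        rows.append(_domtbl_row(protein, plen, acc, evalue, cov, pos, rng))
        pos += MODEL_LENGTHS[acc] + 15
    if rng.random() < straddle_fraction:
        decoy = DECOY_DOMAINS[rng.integers(len(DECOY_DOMAINS))]
        if rng.random() < 0.5:  # fails on e-value, passes coverage
            rows.append(_domtbl_row(protein, plen, decoy, 1.0001e-5, 0.9, 3, rng))
        else:  # passes e-value, fails coverage
            rows.append(_domtbl_row(protein, plen, decoy, 1e-9, 0.69, 3, rng))
    return rows, plen


def generate_hit_tables(
    strains: Sequence[StrainState],
    taxon_map: Mapping[str, str],
    config: SimConfig,
    seed: int = 0,
) -> Tuple[str, str, str]:
    """Emit (domtblout, BLAST outfmt-6, metadata TSV) texts for a corpus.

    Each non-NC strain gets one CDCP whose domain rows realize its profile
    (OTHER = Competence + SLBB); NC strains with a genomic fragment get a
    passing blastn hit, other NC strains occasionally a failing one.
    """
    rng = np.random.default_rng(seed)
    dom_lines = [
        "# target name        accession   tlen query name           accession"
        "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score"
        "  bias  from    to  from    to  from    to  acc description of target"
    ]
    blast_lines: List[str] = []
    meta_lines = ["strain_id\tspecies\ttaxon"]
    other_state_domains = {
        (False, False): (COMPETENCE, "PF10531"),
        (True, False): (DUF4131, COMPETENCE, "PF10531"),
        (False, True): (COMPETENCE, LACTAMASE_B, "PF10531"),
        (True, True): (DUF4131, COMPETENCE, LACTAMASE_B, "PF10531"),
    }
    for s in strains:
        meta_lines.append(f"{s.strain_id}\t{s.species}\t{taxon_map[s.species]}")
        if s.state == "NC":
            if s.genomic_fragment:
                blast_lines.append(
                    f"comec_query\t{s.strain_id}\t"
                    f"{rng.uniform(60, 100):.1f}\t{rng.integers(200, 700)}\t"
                    f"{10 ** rng.uniform(-30, -5):.2g}\t{rng.integers(30, 100)}"
                )
            elif rng.random() < 0.3:  # a near-miss hit, below threshold
                blast_lines.append(
                    f"comec_query\t{s.strain_id}\t"
                    f"{rng.uniform(30, 59):.1f}\t{rng.integers(100, 300)}\t"
                    f"{10 ** rng.uniform(-30, -5):.2g}\t{rng.integers(30, 100)}"
                )
            continue
        if s.state == "OTHER":
            domains = other_state_domains[(s.has_duf4131, s.has_lactamase_b)]
        else:
            domains = _STATE_DOMAINS[s.state]
        rows, _ = _protein_rows(
            s.strain_id, f"{s.strain_id}|P1", domains, rng, config.straddle_fraction
        )
        dom_lines.extend(rows)
    return (
        "\n".join(dom_lines) + "\n",
        "\n".join(blast_lines) + ("\n" if blast_lines else ""),
        "\n".join(meta_lines) + "\n",
    )


# ---------------------------------------------------------------------------
# worked-example and census corpora


def ecoli_example_states(species: str = "Escherichia coli") -> List[StrainState]:
    """The 199-strain oversampled species: 9 NC, 13 CL, 177 DCL strains."""
    states: List[StrainState] = []
    blocks = [("NC", 9), ("CL", 13), ("DCL", 177)]
    i = 0
    for state, count in blocks:
        for _ in range(count):
            i += 1
            states.append(
                StrainState(
                    strain_id=f"ecoli.{i:03d}",
                    species=species,
                    state=state,
                    cdcp_count=0 if state == "NC" else 1,
                    genomic_fragment=(state == "NC"),
                    has_duf4131=(state == "DCL"),
                    has_lactamase_b=(state in ("CL", "DCL")),
                )
            )
    return states


def census_corpus(seed: int = 0) -> Tuple[str, str, str]:
    """A 5,574-strain corpus matching the study's printed counts exactly.

    Proteome-level profiles: 2,000 DCL, 1,279 DC, 583 CL, 1,022 C, 50 OTHER
    (Competence + SLBB) and 640 NC (409 with a genomic fragment). One DCL
    strain carries a second, truncated Competence-only copy, for 4,935 CDCPs
    in 4,934 proteomes with 3,279 DUF4131 and 2,583 Lactamase_B occurrences.
    The 199-strain *E. coli* block (9 NC / 13 CL / 177 DCL) is embedded in
    these totals; every other strain is its own species.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(straddle_fraction=0.05)
    strains: List[StrainState] = []
    taxon_map: Dict[str, str] = {"Escherichia coli": "Gammaproteobacteria"}
    strains.extend(ecoli_example_states())
    remaining = [
        ("DCL", 2000 - 177),
        ("DC", 1279),
        ("CL", 583 - 13),
        ("C", 1022),
        ("OTHER", 50),
        ("NC", 640 - 9),
    ]
    n_rescued_needed = 409 - 9
    i = 0
    n_nc_seen = 0
    for state, count in remaining:
        for _ in range(count):
            i += 1
            species = f"Species{i:04d}"
            taxon_map[species] = f"Taxon{1 + (i % 12)}"
            if state == "NC":
                n_nc_seen += 1
                rescued = n_nc_seen <= n_rescued_needed
            else:
                rescued = False
            strains.append(
                StrainState(
                    strain_id=f"strain{i:04d}",
                    species=species,
                    state=state,
                    cdcp_count=0 if state == "NC" else 1,
                    genomic_fragment=rescued,
                    has_duf4131=state in ("DC", "DCL"),
                    has_lactamase_b=state in ("CL", "DCL"),
                )
            )
    dom_text, blast_text, meta_text = generate_hit_tables(
        strains, taxon_map, config, seed=int(rng.integers(2**31))
    )
    # the one two-CDCP proteome: append a truncated Competence-only copy to
    # the first DCL strain (shorter than the full protein, so never chosen)
    first_dcl = next(s for s in strains if s.state == "DCL")
    extra_rows, _ = _protein_rows(
        first_dcl.strain_id,
        f"{first_dcl.strain_id}|P2",
        (COMPETENCE,),
        np.random.default_rng(seed + 1),
        straddle_fraction=0.0,
        length=300 + 230 * 3 - 330,
    )
    dom_text += "\n".join(extra_rows) + "\n"
    return dom_text, blast_text, meta_text
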