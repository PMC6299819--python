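"""Species-vs-domain cophenetic distance comparison and HGT screening.

For each protein-domain phylogeny (Competence, DUF4131, Lactamase_B), pairs of
strains sharing the same domain profile are compared: the patristic (cophenetic)
distance between the pair in the species tree against the distance in the
domain tree. Domain distances are normalized by the tree's maximum pairwise
distance; species distances by the maximum over CDCP-containing strains only.
An ordinary least-squares regression of domain on species distance summarizes
each profile subset; pairs far *below* the line (domain much closer than the
species history predicts) are candidate horizontal domain acquisitions, pairs
far above are unexpectedly divergent domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple
import logging

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DOMAIN_PROFILE_GROUPS",
    "DistanceMatrix",
    "PairRecord",
    "RegressionFit",
    "cophenetic",
    "normalize_domain",
    "normalize_species",
    "pair_subsets",
    "fit_and_flag",
    "pairs_to_frame",
    "plot_pairs",
]

logger = logging.getLogger(__name__)

#: Profile subsets considered per domain tree: both members of a pair must
#: carry the same profile, and the profile must contain the domain.
DOMAIN_PROFILE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "Competence": ("C", "DC", "DCL", "CL"),
    "DUF4131": ("DC", "DCL"),
    "Lactamase_B": ("CL", "DCL"),
}


@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix over an ordered label list."""

    labels: List[str]
    d: np.ndarray
    normalizer: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def __contains__(self, label: str) -> bool:
        return label in self._index


@dataclass
class PairRecord:
    """One unordered strain pair in one profile subset."""

    strain_a: str
    strain_b: str
    species_distance_norm: float
    domain_distance_norm: float
    subset: str
    residual: float = float("nan")
    outlier_flag: str = "none"  # low | none | high


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.n_pairs < 2:
            raise ValueError("n_pairs < 2")


def cophenetic(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs patristic distances: sum of branch lengths on the path
    a -> LCA(a, b) -> b.

    Single post-order sweep accumulating leaf-to-node distances and combining
    child subtrees at each internal node (O(n^2) total).
    """
    from .trees import validate_tree

    validate_tree(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    # per-node dict: leaf index -> distance from leaf up to this node
    below: Dict[dendropy.Node, Dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {index[node.taxon.label]: 0.0}
            continue
        merged: Dict[int, float] = {}
        for child in node.child_nodes():
            child_dists = below.pop(child)
            edge = child.edge.length or 0.0
            lifted = {leaf: dist + edge for leaf, dist in child_dists.items()}
            for leaf_a, da in lifted.items():
                for leaf_b, db in merged.items():
                    d[leaf_a, leaf_b] = d[leaf_b, leaf_a] = da + db
            merged.update(lifted)
        below[node] = merged
    return DistanceMatrix(labels=labels, d=d, normalizer=1.0)


def normalize_domain(dm: DistanceMatrix) -> DistanceMatrix:
    """Scale all entries by the global maximum pairwise distance."""
    dmax = float(dm.d.max())
    if dmax <= 0:
        raise ValueError("degenerate tree: all pairwise distances are zero")
    return DistanceMatrix(
        labels=list(dm.labels), d=dm.d / dmax, normalizer=dm.normalizer * dmax
    )


def normalize_species(dm: DistanceMatrix, cdcp_strains: Set[str]) -> DistanceMatrix:
    """Scale all entries by the maximum distance among CDCP-containing
    strains; entries involving non-CDCP strains may exceed 1."""
    present = [lab for lab in dm.labels if lab in cdcp_strains]
    if len(present) < 2:
        raise ValueError("need at least two CDCP-containing strains in the tree")
    idx = [dm.labels.index(lab) for lab in present]
    sub = dm.d[np.ix_(idx, idx)]
    dmax = float(sub.max())
    if dmax <= 0:
        raise ValueError("degenerate tree: CDCP subset distances are all zero")
    return DistanceMatrix(
        labels=list(dm.labels), d=dm.d / dmax, normalizer=dm.normalizer * dmax
    )


def pair_subsets(
    species_dm: DistanceMatrix,
    domain_dm: DistanceMatrix,
    strain_states: Mapping[str, str],
    domain: str,
) -> Dict[str, List[PairRecord]]:
    """Group unordered strain pairs by shared profile for one domain tree.

    Only strains present in both trees contribute; domain-tree leaves missing
    from the species tree are dropped with a warning. A strain in the domain
    tree without a profile state is an error.
    """
    if domain not in DOMAIN_PROFILE_GROUPS:
        raise ValueError(f"unknown domain {domain!r}")
    usable = []
    for lab in domain_dm.labels:
        if lab not in species_dm:
            logger.warning("domain-tree leaf %r absent from species tree; dropped", lab)
            continue
        if lab not in strain_states:
            raise KeyError(f"strain {lab!r} in domain tree has no profile state")
        usable.append(lab)
    groups: Dict[str, List[PairRecord]] = {}
    for state in DOMAIN_PROFILE_GROUPS[domain]:
        members = sorted(lab for lab in usable if strain_states[lab] == state)
        subset = f"{domain}/{state}"
        groups[subset] = [
            PairRecord(
                strain_a=a,
                strain_b=b,
                species_distance_norm=species_dm.get(a, b),
                domain_distance_norm=domain_dm.get(a, b),
                subset=subset,
            )
            for a, b in combinations(members, 2)
        ]
    return groups


def fit_and_flag(
    pairs: Sequence[PairRecord], z_threshold: float = 3.0
) -> RegressionFit:
    """OLS of domain distance on species distance; flag outlier pairs.

    Residuals are standardized by their sample SD; pairs with z below
    -*z_threshold* are flagged ``low`` (candidate horizontal acquisition),
    above +*z_threshold* ``high`` (unexpectedly divergent domain). Residual
    and flag are written back onto the records. When the relation is exactly
    linear (residual SD numerically zero) nothing is flagged.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to fit and flag")
    x = np.array([p.species_distance_norm for p in pairs])
    y = np.array([p.domain_distance_norm for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in species distances")
    res = stats.linregress(x, y)
    predicted = res.intercept + res.slope * x
    residuals = y - predicted
    sd = float(np.std(residuals, ddof=1))
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))
    for p, r in zip(pairs, residuals):
        p.residual = float(r)
        if sd <= tol:
            p.outlier_flag = "none"
        elif r < -z_threshold * sd:
            p.outlier_flag = "low"
        elif r > z_threshold * sd:
            p.outlier_flag = "high"
        else:
            p.outlier_flag = "none"
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_pairs=len(pairs),
    )


def pairs_to_frame(groups: Mapping[str, Sequence[PairRecord]]) -> pd.DataFrame:
    rows = []
    for subset in sorted(groups):
        for p in groups[subset]:
            rows.append(
                {
                    "subset": p.subset,
                    "strain_a": p.strain_a,
                    "strain_b": p.strain_b,
                    "species_distance_norm": p.species_distance_norm,
                    "domain_distance_norm": p.domain_distance_norm,
                    "residual": p.residual,
                    "outlier_flag": p.outlier_flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subset",
            "strain_a",
            "strain_b",
            "species_distance_norm",
            "domain_distance_norm",
            "residual",
            "outlier_flag",
        ],
    )


def plot_pairs(
    pairs: Sequence[PairRecord], fit: RegressionFit, path: str, title: str = ""
) -> None:
    """Scatter of normalized domain vs species distances with the fitted
    line; flagged pairs drawn in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.species_distance_norm for p in pairs])
    y = np.array([p.domain_distance_norm for p in pairs])
    flagged = np.array([p.outlier_flag != "none" for p in pairs])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x[~flagged], y[~flagged], s=8, alpha=0.5, color="steelblue")
    if flagged.any():
        ax.scatter(x[flagged], y[flagged], s=14, color="red")
    xs = np.linspace(float(x.min()), float(x.max()), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="black", lw=1)
    ax.set_xlabel("normalized species distance")
    ax.set_ylabel("normalized domain distance")
    label = f"slope={fit.slope:.2f} offset={fit.intercept:.2f} R2={fit.r_squared:.2f}"
    ax.set_title(f"{title}\n{label}" if title else label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
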