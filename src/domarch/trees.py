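"""Shared helpers for rooted, branch-length-bearing phylogenies.

All trees in this package are :class:`dendropy.Tree` objects. These helpers
enforce the invariants the downstream modules rely on: a single root, unique
leaf labels, and non-negative branch lengths.
"""

from __future__ import annotations

import io
from typing import Dict, List

import dendropy

__all__ = [
    "read_tree",
    "tree_from_string",
    "write_tree",
    "tree_to_string",
    "leaf_labels",
    "validate_tree",
    "node_depths",
]


def _load(source: str, is_path: bool) -> dendropy.Tree:
    kwargs = dict(schema="newick", preserve_underscores=True)
    if is_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    validate_tree(tree)
    return tree


def read_tree(path: str) -> dendropy.Tree:
    """Read and validate a rooted Newick tree from *path*."""
    return _load(path, is_path=True)


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse and validate a rooted tree from a Newick string."""
    return _load(newick, is_path=False)


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def write_tree(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_string(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> List[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def validate_tree(tree: dendropy.Tree) -> None:
    """Raise ``ValueError`` on duplicate leaf labels or negative branch lengths."""
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        seen, dups = set(), set()
        for lab in labels:
            (dups if lab in seen else seen).add(lab)
        raise ValueError(f"duplicate leaf labels: {sorted(dups)}")
    for node in tree.preorder_node_iter():
        if node.taxon is None and node.is_leaf():
            raise ValueError("leaf without a label")
        length = node.edge.length
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length}")


def node_depths(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    """Distance from the root to every node (root edge length ignored)."""
    depths: Dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths
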