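"""Array-based view of a dendropy tree for likelihood and simulation code."""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class TreeArrays:
    """Postorder-indexed tree: children lists, branch lengths, leaf labels.

    Nodes are numbered in postorder; the root is the last index.  Leaf
    ``labels[i]`` corresponds to node index ``i`` (leaves occupy the first
    ``n_leaves`` postorder slots only if the tree happens to be laddered, so
    use ``leaf_index`` for lookup).
    """

    children: list[list[int]]          # per node, child node indices
    branch_lengths: np.ndarray         # length of edge above each node (root: 0)
    labels: dict[int, str]             # node index -> leaf label (leaves only)
    n_nodes: int

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_index(self) -> dict[str, int]:
        return {lab: i for i, lab in self.labels.items()}

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[int]:
        """Node indices with a parent edge (all but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]


def tree_to_arrays(tree: dendropy.Tree, default_blen: float = 0.0) -> TreeArrays:
    """Flatten a dendropy tree into postorder arrays.

    Polytomies are kept (pruning handles any out-degree).  Missing branch
    lengths become ``default_blen``.
    """
    index: dict[int, int] = {}
    children: list[list[int]] = []
    blens: list[float] = []
    labels: dict[int, str] = {}
    for i, node in enumerate(tree.postorder_node_iter()):
        index[id(node)] = i
        kids = [index[id(c)] for c in node.child_nodes()]
        children.append(kids)
        blens.append(node.edge.length if node.edge.length is not None else default_blen)
        if node.is_leaf():
            if node.taxon is None or node.taxon.label is None:
                raise ValueError("leaf without a label")
            labels[i] = node.taxon.label
    blens[-1] = 0.0
    return TreeArrays(children, np.asarray(blens, float), labels, len(children))


def set_branch_lengths(tree: dendropy.Tree, arrays: TreeArrays,
                       lengths: np.ndarray) -> None:
    """Write per-edge lengths (postorder order) back onto the dendropy tree."""
    for i, node in enumerate(tree.postorder_node_iter()):
        if i != arrays.root:
            node.edge.length = float(lengths[i])
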