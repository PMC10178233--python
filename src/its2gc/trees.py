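"""Neighbor-joining guide trees on Jukes-Cantor distances, plus newick I/O.

Trees are held as :class:`skbio.TreeNode` objects throughout the package.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alphabet import GAP_CHARS
from .io_seqstruct import SeqStructRecord, SpeciesMatrix


def p_distance(a: str, b: str) -> float:
    """Proportion of differing positions among mutually gap-free positions."""
    comparable = 0
    diff = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable positions between sequences")
    return diff / comparable


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance; saturated at p >= 0.75."""
    if p >= 0.75:
        raise ValueError(f"saturated distance: p = {p:.3f} >= 0.75")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(records: Sequence[SeqStructRecord]) -> DistanceMatrix:
    ids = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for (i, a), (j, b) in combinations(enumerate(records), 2):
        p = p_distance(a.sequence, b.sequence)
        try:
            d[i, j] = d[j, i] = jc_distance(p)
        except ValueError as err:
            raise ValueError(f"{err} (pair {a.id!r} vs {b.id!r})") from None
    return DistanceMatrix(d, ids=ids)


def build_nj_tree(matrix: SpeciesMatrix | Sequence[SeqStructRecord]) -> TreeNode:
    """Neighbor-joining tree on JC-corrected distances.

    Negative NJ branch lengths are clamped to 0.  Deterministic given input
    order.  Two taxa yield a single edge split at the midpoint.
    """
    records = matrix.records if isinstance(matrix, SpeciesMatrix) else list(matrix)
    if len(records) < 2:
        raise ValueError("need >= 2 alleles to build a tree")
    if len(records) == 2:
        a, b = records
        d = jc_distance(p_distance(a.sequence, b.sequence))
        root = TreeNode()
        root.extend(
            [TreeNode(name=a.id, length=d / 2), TreeNode(name=b.id, length=d / 2)]
        )
        return root
    tree = nj(jc_distance_matrix(records), neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def tree_taxa(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def set_branch_lengths(tree: TreeNode, lengths: Sequence[float]) -> None:
    """Assign branch lengths to non-root nodes in postorder (for optimizers)."""
    nodes = [n for n in tree.postorder() if not n.is_root()]
    if len(nodes) != len(lengths):
        raise ValueError("length vector does not match tree edges")
    for node, ell in zip(nodes, lengths):
        node.length = float(ell)


def get_branch_lengths(tree: TreeNode) -> np.ndarray:
    return np.array(
        [n.length or 0.0 for n in tree.postorder() if not n.is_root()], dtype=float
    )
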