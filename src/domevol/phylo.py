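"""Distance-based tree building and tree I/O.

Neighbor joining over a p-distance matrix serves as a light-weight surrogate
for full Bayesian inference: good enough for topology checks on simulated
data and for producing a newick tree from a family MSA. Externally produced
trees can be read in for reporting.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import DomevolError


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration (Q-criterion); negative branch lengths are
    clamped to zero."""
    if len(dm.ids) < 3:
        raise DomevolError("need at least 3 taxa")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(_stdio.StringIO(text), format="newick")


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each canonicalized as
    the side not containing an arbitrary fixed reference leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = leaves - side
        parts.add(frozenset(side))
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Number of non-trivial bipartitions present in exactly one tree."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise DomevolError("trees have different leaf sets")
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2)
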