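"""Robinson–Foulds comparison of inferred and true tree topologies.

Trees are compared as rooted (the histories are rooted at the diploid
ancestor): each internal vertex below the root defines a clade — the set of
leaf labels under it — and the distance is the size of the symmetric
difference of the two clade sets, normalized by the total number of
nontrivial clades in both trees so that 0 means identical topologies and 1
means no shared clade. For two full binary trees on k leaves the
denominator is 2(k - 2). An unrooted variant over bipartitions is provided
for sensitivity checks.
"""

from __future__ import annotations

from .core import CopyNumberTree

__all__ = ["topology_from_tree", "nontrivial_clades", "normalized_rf"]

#: A leaf-labeled topology: nested tuples of leaf-label strings.
Topology = tuple | str


def topology_from_tree(tree: CopyNumberTree, drop_auxiliary: bool = True) -> Topology:
    """Extract the leaf topology of a copy-number tree as nested tuples.

    Auxiliary leaves (the appended all-diploid clone) are removed by default
    and their attachment vertices suppressed.
    """

    def build(v):
        kids = tree.children.get(v, ())
        if not kids:
            if drop_auxiliary and v in tree.auxiliary_leaves:
                return None
            return tree.leaf_labels.get(v, str(v))
        parts = [build(c) for c in kids]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return tuple(parts)

    top = build(tree.root)
    if top is None or isinstance(top, str):
        raise ValueError("topology needs at least two non-auxiliary leaves")
    return top


def _leaves(t: Topology) -> frozenset[str]:
    if isinstance(t, str):
        return frozenset([t])
    return frozenset().union(*(_leaves(c) for c in t))


def nontrivial_clades(t: Topology) -> set[frozenset[str]]:
    """Leaf-label sets of internal vertices, excluding the root set and singletons."""
    clades: set[frozenset[str]] = set()

    def walk(sub) -> frozenset[str]:
        if isinstance(sub, str):
            return frozenset([sub])
        below = frozenset().union(*(walk(c) for c in sub))
        clades.add(below)
        return below

    everything = walk(t)
    clades.discard(everything)
    return {c for c in clades if len(c) > 1}


def _bipartitions(t: Topology) -> set[frozenset[frozenset[str]]]:
    """Nontrivial unrooted splits: each clade against its complement."""
    everything = _leaves(t)
    out = set()
    for clade in nontrivial_clades(t):
        comp = everything - clade
        if len(comp) > 1:
            out.add(frozenset([clade, comp]))
    return out


def normalized_rf(t1: Topology, t2: Topology, rooted: bool = True) -> float:
    """Symmetric-difference clade distance scaled to [0, 1].

    0 iff the rooted topologies are identical (for full binary trees); the
    denominator is the summed nontrivial clade (or split) counts of both
    trees, and the value is defined as 0 when both sets are empty (two-leaf
    trees).
    """
    if _leaves(t1) != _leaves(t2):
        raise ValueError("trees have different leaf label sets")
    if rooted:
        c1, c2 = nontrivial_clades(t1), nontrivial_clades(t2)
    else:
        c1, c2 = _bipartitions(t1), _bipartitions(t2)
    denom = len(c1) + len(c2)
    if denom == 0:
        return 0.0
    return len(c1 ^ c2) / denom
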