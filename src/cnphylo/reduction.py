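"""Hardness gadget: maximum parsimony phylogeny encoded as a copy-number tree.

Binary-vector parsimony (MPP: full binary tree, leaves given, root all-0's,
Hamming edge costs) embeds into the copy-number tree problem with cap
e = 2: each binary value maps to a copy number (1 for 1, 2 for 0) and the n
true positions are separated by *walls* — alternating (2, 1) buffers of
length nk whose initialization costs W = (n-1)nk/2 and whose purpose is to
stop a single event from spanning two true positions. An all-diploid extra
profile lets the walls initialize on one shared edge below the root.

For an MPP optimum h, the encoded instance always admits a copy-number tree
of cost h + W (flips become unit events on true positions). The converse
accounting is an asymptotic argument: at very small n the walls are cheap
enough that a copy-number tree can undercut h + W, e.g. by sliding an event
across a wall boundary or relabeling the subtree root, so equality should
only be expected once n is large enough for walls to dominate.

A tiny-scale exhaustive MPP solver is included as the cross-problem oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import Profile
from .cnt_ilp import CntInstance, _all_topologies
from .distance import INF

__all__ = ["MppInstance", "WallLayout", "encode_profile", "mpp_to_cnt",
           "wall_cost", "mpp_brute_force"]


@dataclass(frozen=True)
class MppInstance:
    """k binary vectors of common length n; root of the sought tree is all-0."""

    vectors: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if len(self.vectors) < 2:
            raise ValueError("need at least two vectors")
        n = len(self.vectors[0])
        if any(len(b) != n for b in self.vectors):
            raise ValueError("vectors must have equal length")
        if any(x not in (0, 1) for b in self.vectors for x in b):
            raise ValueError("vectors must be binary")

    @property
    def k(self) -> int:
        return len(self.vectors)

    @property
    def n(self) -> int:
        return len(self.vectors[0])


@dataclass(frozen=True)
class WallLayout:
    """Coordinate bookkeeping for the wall construction."""

    n: int
    k: int

    @property
    def wall_len(self) -> int:
        return self.n * self.k

    @property
    def total_len(self) -> int:
        return self.n + (self.n - 1) * self.wall_len

    def alpha(self, s: int) -> int:
        """Transformed coordinate of true position s (1-based)."""
        if not 1 <= s <= self.n:
            raise ValueError(f"true position {s} out of range")
        return s + (s - 1) * self.wall_len


def wall_cost(n: int, k: int) -> int:
    """W = (n-1)nk/2 — the shared cost of initializing all wall buffers."""
    return (n - 1) * n * k // 2


def encode_profile(b: tuple[int, ...], layout: WallLayout) -> Profile:
    """phi(b_1) Omega phi(b_2) ... : 1 for a set bit, 2 otherwise, walls between."""
    if len(b) != layout.n:
        raise ValueError("vector length does not match the layout")
    wall = tuple(2 if j % 2 == 1 else 1 for j in range(1, layout.wall_len + 1))
    out: list[int] = []
    for s, bit in enumerate(b, start=1):
        if s > 1:
            out.extend(wall)
        out.append(1 if bit == 1 else 2)
    return tuple(out)


def mpp_to_cnt(inst: MppInstance) -> CntInstance:
    """Encode an MPP instance as a copy-number tree instance with cap e = 2.

    Produces k+1 profiles of length n + (n-1)nk: the encoded vectors plus an
    all-diploid profile (the image of the all-0 root).
    """
    layout = WallLayout(inst.n, inst.k)
    profiles = tuple(encode_profile(b, layout) for b in inst.vectors)
    profiles += (tuple([2] * layout.total_len),)
    ids = tuple(f"b{i + 1}" for i in range(inst.k)) + ("all2",)
    return CntInstance(profiles, 2, ids=ids)


def mpp_brute_force(inst: MppInstance, max_leaves: int = 4) -> int:
    """Exact MPP optimum by exhaustive topology + labeling search.

    Enumerates every rooted full binary leaf-labeled topology on k leaves
    and solves the internal labeling exactly over {0,1}^n by dynamic
    programming on the tree (Hamming edge costs, root forced all-0).
    """
    k, n = inst.k, inst.n
    if k > max_leaves:
        raise ValueError(f"too many leaves ({k}) for brute force")
    alphabet = list(product((0, 1), repeat=n))
    idx = {b: i for i, b in enumerate(alphabet)}
    A = len(alphabet)
    ham = np.array(
        [[sum(x != y for x, y in zip(p, q)) for q in alphabet] for p in alphabet],
        dtype=np.int64,
    )
    leaf_state = [idx[tuple(b)] for b in inst.vectors]
    root = idx[tuple([0] * n)]

    def vec(t) -> np.ndarray:
        if not isinstance(t, tuple):
            out = np.full(A, INF, dtype=np.int64)
            out[leaf_state[t]] = 0
            return out
        left, right = t
        vl, vr = vec(left), vec(right)
        return (
            np.minimum(ham + vl[None, :], INF).min(axis=1)
            + np.minimum(ham + vr[None, :], INF).min(axis=1)
        )

    return int(min(min(vec(shape)[root] for shape in _all_topologies(k)), INF))
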