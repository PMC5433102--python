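"""Minimum-cost one-directional distance between two copy-number profiles.

The distance from p to q is the minimum total cost of an event sequence
transforming p into q; it is asymmetric (a lost position cannot be regained)
and may be infinite. It is computed by a dynamic program over per-position
deletion/amplification budgets (d, a), both bounded by the maximum input copy
number B: G[i, d, a] is the minimum cost of a sequence turning the length-i
prefix of p into that of q while exactly d deletion units and a amplification
units cover position i. An independent breadth-first-search oracle over the
full profile state space is provided for verification at tiny sizes.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np

from .core import Profile, as_profile

__all__ = [
    "INF",
    "max_copy_bound",
    "distance_table",
    "distance",
    "distance_bfs_oracle",
]

#: Sentinel strictly greater than any feasible cost (feasible costs <= 2 n B).
INF = 10**9


def max_copy_bound(u: Sequence[int], v: Sequence[int]) -> int:
    """B = maximum copy number over both profiles (the DP budget bound)."""
    u, v = as_profile(u), as_profile(v)
    if len(u) != len(v):
        raise ValueError("profiles must have equal length")
    return max(max(u), max(v))


def _budget_transform(g: np.ndarray, axis: int) -> np.ndarray:
    """min over x' of g[..., x', ...] + max(x - x', 0), along ``axis``.

    Equals min(suffix-min of g, x + prefix-min of (g - x')): one backward and
    one forward scan, so the min over a (B+1)-point axis costs O(B).
    """
    g = np.moveaxis(g, axis, -1)
    m = g.shape[-1]
    suffix = np.minimum.accumulate(g[..., ::-1], axis=-1)[..., ::-1]
    shifted = g - np.arange(m)
    prefix = np.minimum.accumulate(shifted, axis=-1) + np.arange(m)
    return np.moveaxis(np.minimum(suffix, prefix), -1, axis)


def _infeasible_mask(p_i: int, q_i: int, B: int) -> np.ndarray:
    """Boolean (B+1, B+1) mask over (d, a) of states ruled out at a position."""
    d = np.arange(B + 1)[:, None]
    a = np.arange(B + 1)[None, :]
    if q_i > 0:
        return (d >= p_i) | (q_i != p_i - d + a)
    return np.broadcast_to(d < p_i, (B + 1, B + 1))


def distance_table(p: Sequence[int], q: Sequence[int], B: int | None = None) -> np.ndarray:
    """The full (n, B+1, B+1) budget table G for the prefix dynamic program.

    Entries are INF where no sequence with the given per-position budgets
    exists. Position 1 costs d + a outright; later positions pay only the
    budget increments max(d - d', 0) + max(a - a', 0) over the best
    predecessor state, because an event covering position i can be extended
    backwards from position i-1 for free.
    """
    p, q = as_profile(p), as_profile(q)
    if len(p) != len(q):
        raise ValueError("profiles must have equal length")
    if B is None:
        B = max_copy_bound(p, q)
    n = len(p)
    G = np.empty((n, B + 1, B + 1), dtype=np.int64)
    d = np.arange(B + 1)[:, None]
    a = np.arange(B + 1)[None, :]
    base = d + a
    G[0] = np.where(_infeasible_mask(p[0], q[0], B), INF, base)
    for i in range(1, n):
        prev = np.minimum(G[i - 1], INF)
        best = _budget_transform(_budget_transform(prev, 0), 1)
        G[i] = np.where(_infeasible_mask(p[i], q[i], B), INF, np.minimum(best, INF))
    return G


def distance(p: Sequence[int], q: Sequence[int]) -> int:
    """Minimum event cost to transform p into q; INF if impossible.

    Finite exactly when every zero entry of p is also zero in q.
    """
    G = distance_table(p, q)
    best = int(G[-1].min())
    return INF if best >= INF else best


def distance_bfs_oracle(p: Sequence[int], q: Sequence[int], cap: int | None = None,
                        max_states: int = 200_000) -> int:
    """Shortest path from p to q where moves are all unit events (s, t, +-1).

    Independent of the dynamic program: explores the graph of profiles with
    entries in 0..cap by breadth-first search (all arcs have weight 1).
    Intended for exhaustive verification on tiny state spaces only.
    """
    p, q = as_profile(p), as_profile(q)
    if len(p) != len(q):
        raise ValueError("profiles must have equal length")
    if cap is None:
        cap = max(max(p), max(q))
    n = len(p)
    if (cap + 1) ** n > max_states:
        raise ValueError(f"state space ({cap + 1}^{n}) exceeds {max_states}")
    if p == q:
        return 0
    dist: dict[Profile, int] = {p: 0}
    queue: deque[Profile] = deque([p])
    while queue:
        cur = queue.popleft()
        for s in range(n):
            for t in range(s, n):
                for b in (-1, 1):
                    nxt = tuple(
                        max(v + b, 0) if (s <= i <= t and v != 0) else v
                        for i, v in enumerate(cur)
                    )
                    if max(nxt) > cap or nxt in dist:
                        continue
                    dist[nxt] = dist[cur] + 1
                    if nxt == q:
                        return dist[nxt]
                    queue.append(nxt)
    return INF
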