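"""The copy-number triplet (median) problem.

Given two profiles u and v, find a parental profile m and two event
sequences turning m into u and into v whose total cost is minimum. The
optimum Delta(u, v) is symmetric and always finite (the all-max profile is a
feasible parent). Two dynamic programs are provided:

* :func:`cn3_alg1` — the full table ``L[i, m, d_u, a_u, d_v, a_v]`` over the
  parent value m at position i and the four per-position deletion /
  amplification budgets, all bounded by the maximum input copy number B. The
  table is retained so an optimal median and sorted event sequences can be
  traced back.
* :func:`cn3_alg2` — a cost-only variant that stores only budget
  combinations consistent with the per-position arithmetic (when u_i > 0 the
  amplification budget is determined by ``a_u = u_i - m + d_u``) and
  restricts predecessor enumeration accordingly; asymptotically faster and
  used as a cross-check.

An exhaustive oracle (:func:`cn3_brute_oracle`) enumerates every candidate
median over a tiny grid and prices both arms with the unit-event
breadth-first search, independent of either dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .core import Event, EventSequence, Profile, apply_sequence, as_profile, is_sorted, sequence_cost
from .distance import INF, _budget_transform, distance_bfs_oracle, max_copy_bound

__all__ = [
    "Cn3Solution",
    "strip_common_zeros",
    "cn3_alg1",
    "cn3_alg2",
    "cn3_traceback",
    "cn3_solve",
    "cn3_brute_oracle",
]


@dataclass
class Cn3Solution:
    """A median profile together with sorted event sequences to each child."""

    median: Profile
    seq_to_u: EventSequence
    seq_to_v: EventSequence
    cost: int

    def check(self, u: Sequence[int], v: Sequence[int]) -> None:
        """Raise if the solution does not actually connect median to u and v."""
        u, v = as_profile(u), as_profile(v)
        if apply_sequence(self.median, self.seq_to_u) != u:
            raise AssertionError("median sequence does not reproduce u")
        if apply_sequence(self.median, self.seq_to_v) != v:
            raise AssertionError("median sequence does not reproduce v")
        if sequence_cost(self.seq_to_u) + sequence_cost(self.seq_to_v) != self.cost:
            raise AssertionError("sequence costs do not sum to the reported cost")
        if not (is_sorted(self.seq_to_u) and is_sorted(self.seq_to_v)):
            raise AssertionError("sequences are not sorted (deletions first)")


def strip_common_zeros(u: Sequence[int], v: Sequence[int]):
    """Drop positions where both profiles are zero (the median is zero there).

    Returns the reduced profiles (possibly empty tuples) and a map from
    reduced position (1-based) to original position (1-based). The optimum is
    unchanged: a jointly-lost position is inherited lost at zero cost.
    """
    u, v = tuple(int(x) for x in u), tuple(int(x) for x in v)
    if len(u) != len(v):
        raise ValueError("profiles must have equal length")
    keep = [i for i in range(len(u)) if u[i] != 0 or v[i] != 0]
    pos_map = {r + 1: i + 1 for r, i in enumerate(keep)}
    return tuple(u[i] for i in keep), tuple(v[i] for i in keep), pos_map


def _level_mask(u_i: int, v_i: int, B: int) -> np.ndarray:
    """(B+1,)**5 boolean mask of infeasible (m, d_u, a_u, d_v, a_v) states."""
    m = np.arange(B + 1).reshape(-1, 1, 1, 1, 1)
    du = np.arange(B + 1).reshape(1, -1, 1, 1, 1)
    au = np.arange(B + 1).reshape(1, 1, -1, 1, 1)
    dv = np.arange(B + 1).reshape(1, 1, 1, -1, 1)
    av = np.arange(B + 1).reshape(1, 1, 1, 1, -1)
    if u_i > 0:
        bad = (du >= m) | (u_i != m - du + au)
    else:
        bad = du < m
    if v_i > 0:
        bad = bad | (dv >= m) | (v_i != m - dv + av)
    else:
        bad = bad | (dv < m)
    return bad


def cn3_alg1(u: Sequence[int], v: Sequence[int], e: int | None = None):
    """Full-table dynamic program; returns (cost, table stack).

    ``table[i]`` has axes (m, d_u, a_u, d_v, a_v), each 0..B. Position 1 costs
    the sum of its four budgets; later positions pay only budget increments
    over the best predecessor state (the parent value m' ranges over
    0..min(B, e)). The optional cap ``e`` bounds the median's entries; by
    default only the structural bound B applies.
    """
    u, v = as_profile(u) if len(u) else (), as_profile(v) if len(v) else ()
    if len(u) != len(v):
        raise ValueError("profiles must have equal length")
    n = len(u)
    if n == 0:
        return 0, np.zeros((0, 1, 1, 1, 1, 1), dtype=np.int64)
    B = max_copy_bound(u, v)
    cap = B if e is None else min(B, e)
    if B == 0:  # both profiles all-zero: the zero median costs nothing
        return 0, np.zeros((n, 1, 1, 1, 1, 1), dtype=np.int64)
    shape = (B + 1,) * 5
    L = np.empty((n,) + shape, dtype=np.int64)
    idx = np.arange(B + 1)
    base = (
        idx.reshape(-1, 1, 1, 1)
        + idx.reshape(1, -1, 1, 1)
        + idx.reshape(1, 1, -1, 1)
        + idx.reshape(1, 1, 1, -1)
    )[None]  # d_u + a_u + d_v + a_v, broadcast over m
    L[0] = np.where(_level_mask(u[0], v[0], B), INF, base)
    for i in range(1, n):
        prev = L[i - 1][: cap + 1].min(axis=0)  # min over allowed m'
        best = prev
        for ax in range(4):
            best = _budget_transform(best, ax)
        best = np.minimum(best, INF)[None]
        L[i] = np.where(_level_mask(u[i], v[i], B), INF, best)
    cost = int(L[n - 1][: cap + 1].min())
    return cost, L


def _alg2_feasible(u_i: int, v_i: int, B: int, cap: int):
    """Yield feasible (m, d_u, a_u, d_v, a_v) coordinates at one position."""
    for m in range(cap + 1):
        if u_i > 0:
            dus = [(du, u_i - m + du) for du in range(min(m, B + 1)) if 0 <= u_i - m + du <= B]
        else:
            dus = [(du, au) for du in range(m, B + 1) for au in range(B + 1)]
        if v_i > 0:
            dvs = [(dv, v_i - m + dv) for dv in range(min(m, B + 1)) if 0 <= v_i - m + dv <= B]
        else:
            dvs = [(dv, av) for dv in range(m, B + 1) for av in range(B + 1)]
        for du, au in dus:
            for dv, av in dvs:
                yield m, du, au, dv, av


def cn3_alg2(u: Sequence[int], v: Sequence[int], e: int | None = None) -> int:
    """Cost-only dynamic program with budget-compressed storage.

    Only coordinates consistent with the per-position arithmetic are stored
    (a pruned coordinate is implicitly infinite). Predecessor enumeration is
    restricted: when the previous u-value is positive, its amplification
    budget is determined by ``a_u' = u_{i-1} - m' + d_u'``; when it is zero,
    the deletion budget can be fixed at ``max(d_u, m')`` and the
    amplification budget carried over unchanged (events covering position i
    extend freely across the lost position i-1). Symmetrically for v.
    """
    u, v = tuple(int(x) for x in u), tuple(int(x) for x in v)
    if len(u) != len(v):
        raise ValueError("profiles must have equal length")
    n = len(u)
    if n == 0:
        return 0
    B = max(max(u), max(v))
    if B == 0:
        return 0
    cap = B if e is None else min(B, e)
    prev: dict[tuple[int, int, int, int, int], int] = {}
    for coord in _alg2_feasible(u[0], v[0], B, cap):
        m, du, au, dv, av = coord
        prev[coord] = du + au + dv + av
    for i in range(1, n):
        up, vp = u[i - 1], v[i - 1]
        cur: dict[tuple[int, int, int, int, int], int] = {}
        for coord in _alg2_feasible(u[i], v[i], B, cap):
            _, du, au, dv, av = coord
            best = INF
            for mp in range(cap + 1):
                if up > 0:
                    dups = range(B + 1)
                else:
                    dups = (max(du, mp),)
                for dup in dups:
                    aup = up - mp + dup if up > 0 else au
                    if not 0 <= aup <= B:
                        continue
                    if vp > 0:
                        dvps = range(B + 1)
                    else:
                        dvps = (max(dv, mp),)
                    for dvp in dvps:
                        avp = vp - mp + dvp if vp > 0 else av
                        if not 0 <= avp <= B:
                            continue
                        val = prev.get((mp, dup, aup, dvp, avp))
                        if val is None:
                            continue
                        val += (
                            max(du - dup, 0)
                            + max(au - aup, 0)
                            + max(dv - dvp, 0)
                            + max(av - avp, 0)
                        )
                        if val < best:
                            best = val
            if best < INF:
                cur[coord] = best
        prev = cur
    return min(prev.values()) if prev else 0


def _skyline(track: Sequence[int], b: int) -> list[Event]:
    """Decompose a per-position coverage track into maximal-run unit events."""
    events: list[Event] = []
    top = max(track, default=0)
    for level in range(1, top + 1):
        s = None
        for i, c in enumerate(track, start=1):
            if c >= level and s is None:
                s = i
            elif c < level and s is not None:
                events.append(Event(s, i - 1, b))
                s = None
        if s is not None:
            events.append(Event(s, len(track), b))
    return events


def cn3_traceback(L: np.ndarray, u: Sequence[int], v: Sequence[int],
                  e: int | None = None) -> Cn3Solution:
    """Recover an optimal median and sorted event sequences from the full table.

    Ties are broken toward the lexicographically smallest coordinate vector,
    so the traceback is deterministic. The per-position budget tracks are
    turned into unit events by skyline decomposition (each maximal run at
    each coverage level is one event), deletions before amplifications.
    """
    u, v = tuple(int(x) for x in u), tuple(int(x) for x in v)
    n = len(u)
    if n == 0:
        return Cn3Solution((), (), (), 0)
    B = max(max(u), max(v))
    if B == 0:
        return Cn3Solution(tuple([0] * n), (), (), 0)
    cap = B if e is None else min(B, e)
    final = L[n - 1][: cap + 1]
    cost = int(final.min())
    cur = min(zip(*np.nonzero(final == cost)))  # lexicographically smallest
    states = [tuple(int(x) for x in cur)]
    for i in range(n - 1, 0, -1):
        m, du, au, dv, av = states[-1]
        target = int(L[i][m, du, au, dv, av])
        found = None
        for mp in range(cap + 1):
            for dup, aup, dvp, avp in product(range(B + 1), repeat=4):
                val = int(L[i - 1][mp, dup, aup, dvp, avp])
                if val >= INF:
                    continue
                inc = (
                    max(du - dup, 0) + max(au - aup, 0)
                    + max(dv - dvp, 0) + max(av - avp, 0)
                )
                if val + inc == target:
                    found = (mp, dup, aup, dvp, avp)
                    break
            if found:
                break
        if found is None:  # pragma: no cover - table inconsistency
            raise RuntimeError("traceback failed: no consistent predecessor")
        states.append(found)
    states.reverse()
    median = tuple(st[0] for st in states)
    du_track = [st[1] for st in states]
    au_track = [st[2] for st in states]
    dv_track = [st[3] for st in states]
    av_track = [st[4] for st in states]
    seq_u = tuple(_skyline(du_track, -1) + _skyline(au_track, +1))
    seq_v = tuple(_skyline(dv_track, -1) + _skyline(av_track, +1))
    return Cn3Solution(median, seq_u, seq_v, cost)


def cn3_solve(u: Sequence[int], v: Sequence[int], e: int | None = None) -> Cn3Solution:
    """Solve the triplet problem end to end on unreduced input.

    Positions where both children are zero are stripped first (the median is
    zero there) and event coordinates are mapped back afterwards; an event
    whose run spans a stripped position is safe because the median is frozen
    at zero there.
    """
    ru, rv, pos_map = strip_common_zeros(u, v)
    n = len(u)
    if len(ru) == 0:
        return Cn3Solution(tuple([0] * n), (), (), 0)
    cost, L = cn3_alg1(ru, rv, e=e)
    sol = cn3_traceback(L, ru, rv, e=e)
    median = [0] * n
    for r, i in pos_map.items():
        median[i - 1] = sol.median[r - 1]

    def remap(seq: EventSequence) -> EventSequence:
        return tuple(Event(pos_map[ev.s], pos_map[ev.t], ev.b) for ev in seq)

    out = Cn3Solution(tuple(median), remap(sol.seq_to_u), remap(sol.seq_to_v), cost)
    out.check(tuple(int(x) for x in u), tuple(int(x) for x in v))
    return out


def cn3_brute_oracle(u: Sequence[int], v: Sequence[int], max_space: int = 100_000) -> int:
    """Exhaustive minimum over candidate medians, priced by the BFS oracle.

    Candidate medians take values 1..B at positions where either child is
    positive and 0 where both are zero. Independent of both dynamic programs.
    """
    u, v = tuple(int(x) for x in u), tuple(int(x) for x in v)
    ru, rv, _ = strip_common_zeros(u, v)
    n = len(ru)
    if n == 0:
        return 0
    B = max(max(ru), max(rv))
    if (B + 1) ** n > max_space:
        raise ValueError("median search space too large for brute force")
    best = INF
    for m in product(range(1, B + 1), repeat=n):
        c = distance_bfs_oracle(m, ru, cap=B) + distance_bfs_oracle(m, rv, cap=B)
        best = min(best, c)
    return best
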