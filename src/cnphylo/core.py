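"""Event model for copy-number profile evolution.

A *profile* is an integer vector giving the number of copies of each of n
contiguous genomic positions in one clone. An *event* ``(s, t, b)`` adds ``b``
(clamped below at zero) to every currently nonzero entry in the 1-based
inclusive interval ``[s, t]``: an amplification if ``b > 0``, a deletion if
``b < 0``. Its cost is ``|b|``. A position whose copy number reaches zero is
lost for good — no later event can change it. Evolutionary histories are
rooted full binary trees whose vertices carry profiles, whose root is diploid
(all 2's), and whose edges carry ordered event sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Profile",
    "Event",
    "EventSequence",
    "CopyNumberTree",
    "as_profile",
    "apply_event",
    "apply_sequence",
    "sequence_cost",
    "to_unit_events",
    "is_sorted",
    "tree_cost",
    "validate_tree",
]

#: A profile is an immutable tuple of non-negative copy counts.
Profile = tuple[int, ...]


class Event(NamedTuple):
    """A segmental copy-number event on the closed interval ``[s, t]`` (1-based)."""

    s: int
    t: int
    b: int


#: Ordered sequence of events; order matters because events interact through
#: the zero-clamping rule.
EventSequence = tuple[Event, ...]


def as_profile(values: Iterable[int]) -> Profile:
    """Validate and freeze a copy-number vector."""
    p = tuple(int(v) for v in values)
    if len(p) == 0:
        raise ValueError("a profile must have at least one position")
    if any(v < 0 for v in p):
        raise ValueError(f"copy numbers must be non-negative, got {p}")
    return p


def _check_event(ev: Event, n: int) -> None:
    if not (1 <= ev.s <= ev.t <= n):
        raise ValueError(f"event {ev} out of range for profile of length {n}")
    if ev.b == 0:
        raise ValueError(f"event {ev} has zero magnitude")


def apply_event(p: Sequence[int], ev: Event) -> Profile:
    """Apply one event: entries in [s, t] that are nonzero become max(v + b, 0).

    Zero entries are frozen — a lost position can never be regained.
    """
    ev = Event(*ev)
    _check_event(ev, len(p))
    return tuple(
        max(v + ev.b, 0) if (ev.s <= i <= ev.t and v != 0) else v
        for i, v in enumerate(p, start=1)
    )


def apply_sequence(p: Sequence[int], seq: Iterable[Event]) -> Profile:
    """Left fold of :func:`apply_event` in sequence order."""
    out = tuple(p)
    for ev in seq:
        out = apply_event(out, ev)
    return out


def sequence_cost(seq: Iterable[Event]) -> int:
    """Total cost of a sequence: the sum of |b| over its events."""
    return sum(abs(ev[2]) for ev in seq)


def to_unit_events(seq: Iterable[Event]) -> EventSequence:
    """Replace each event (s, t, b) by |b| copies of (s, t, sign(b)).

    The decomposition preserves both total cost and the effect on any profile:
    clamping at zero commutes with splitting a deletion into unit deletions,
    and amplifications never clamp.
    """
    out: list[Event] = []
    for ev in seq:
        ev = Event(*ev)
        step = 1 if ev.b > 0 else -1
        out.extend(Event(ev.s, ev.t, step) for _ in range(abs(ev.b)))
    return tuple(out)


def is_sorted(seq: Iterable[Event]) -> bool:
    """True iff all deletions precede all amplifications."""
    seen_amp = False
    for ev in seq:
        if ev[2] > 0:
            seen_amp = True
        elif seen_amp:
            return False
    return True


@dataclass
class CopyNumberTree:
    """Rooted full binary tree with profile-labeled vertices and event-labeled edges.

    Vertices are integer ids. ``children`` maps each internal vertex to its
    ordered pair of children; ``events`` labels each (parent, child) edge with
    an ordered event sequence; ``leaf_labels`` maps leaf vertex ids to sample
    identifiers. ``auxiliary_leaves`` marks leaves that were appended to the
    instance (an all-diploid companion clone) rather than observed.
    """

    root: int
    profiles: dict[int, Profile]
    children: dict[int, tuple[int, ...]] = field(default_factory=dict)
    events: dict[tuple[int, int], EventSequence] = field(default_factory=dict)
    leaf_labels: dict[int, str] = field(default_factory=dict)
    auxiliary_leaves: set[int] = field(default_factory=set)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, kids in self.children.items() for v in kids]

    def leaves(self) -> list[int]:
        return [v for v in self.profiles if not self.children.get(v)]

    def parent_of(self) -> dict[int, int]:
        return {v: u for u, v in self.edges()}


def tree_cost(t: CopyNumberTree) -> int:
    """Sum of edge sequence costs over the whole tree."""
    return sum(sequence_cost(seq) for seq in t.events.values())


def validate_tree(t: CopyNumberTree, instance=None) -> list[str]:
    """Check every structural condition of a copy-number tree; return violations.

    All violations are collected (not raised) so a decoded solver tree can be
    inspected as a whole. ``instance`` is any object with ``profiles`` (the
    ordered leaf profiles) and ``e`` (the copy-number cap); when given, leaf
    labels and the cap are checked too.
    """
    errs: list[str] = []
    for u, kids in t.children.items():
        if len(kids) not in (0, 2):
            errs.append(f"vertex {u} has {len(kids)} children; tree is not full binary")
    if t.root not in t.profiles:
        errs.append("root has no profile")
        return errs
    n = len(t.profiles[t.root])
    if any(v != 2 for v in t.profiles[t.root]):
        errs.append(f"root not diploid: {t.profiles[t.root]}")
    for (u, v), seq in t.events.items():
        got = apply_sequence(t.profiles[u], seq)
        if got != t.profiles[v]:
            errs.append(
                f"edge ({u},{v}) inconsistent: events yield {got}, vertex labeled {t.profiles[v]}"
            )
    for u, kids in t.children.items():
        for v in kids:
            if (u, v) not in t.events:
                errs.append(f"edge ({u},{v}) has no event sequence")
    reach = set()
    stack = [t.root]
    while stack:
        u = stack.pop()
        reach.add(u)
        stack.extend(t.children.get(u, ()))
    if reach != set(t.profiles):
        errs.append("not all vertices reachable from the root")
    if instance is not None:
        e = instance.e
        for v, p in t.profiles.items():
            if len(p) != n:
                errs.append(f"vertex {v} profile length {len(p)} != {n}")
            if max(p) > e:
                errs.append(f"vertex {v} exceeds copy-number cap {e}: {p}")
        ids = getattr(instance, "sample_ids", None)
        ids = list(ids()) if callable(ids) else None
        want = [as_profile(c) for c in instance.profiles]
        if ids is not None and set(ids) == {t.leaf_labels.get(v) for v in t.leaves()}:
            by_id = dict(zip(ids, want))
            for v in t.leaves():
                if t.profiles[v] != by_id[t.leaf_labels[v]]:
                    errs.append(
                        f"leaf {v} ({t.leaf_labels[v]}) labeled {t.profiles[v]}, "
                        f"instance says {by_id[t.leaf_labels[v]]}"
                    )
        elif sorted(t.profiles[v] for v in t.leaves()) != sorted(want):
            errs.append("leaf profiles do not match the instance profiles")
    return errs
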