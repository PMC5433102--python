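"""Ground-truthed instance generator for the copy-number tree problem.

Emulates clonal evolution by segmental events: a random full binary tree
with k leaves is grown from the diploid root; each edge receives d events
with d uniform on {1..m}; each event's interval [s, t] is uniform over the
n(n+1)/2 pairs s <= t and its sign is +1 (amplification) with probability
rho, else -1 (deletion). Profiles are propagated root-to-leaf; the
copy-number cap e of the resulting instance is the maximum observed leaf
value, floored at 2 so the diploid root is representable.

Drawn events that land entirely on already-lost positions still count
toward the recorded simulated cost — the inferred parsimony cost can
therefore undercut the simulated one. Internal ancestral profiles may
exceed the leaf-derived cap e; only the leaves define the instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CopyNumberTree, Event, apply_sequence, sequence_cost
from .cnt_ilp import CntInstance

__all__ = ["SimulationConfig", "SimulatedInstance", "random_topology",
           "random_events", "generate_instance"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study condition knobs: k leaves, n positions, <= m events/edge, amp ratio rho."""

    k: int
    n: int
    m: int
    rho: float
    seed: int

    def __post_init__(self):
        if self.k < 2 or self.n < 1 or self.m < 1 or not 0 <= self.rho <= 1:
            raise ValueError(f"invalid simulation config {self}")


@dataclass
class SimulatedInstance:
    """A solver-ready instance bundled with its generating tree and true cost."""

    config: SimulationConfig
    instance: CntInstance
    truth: CopyNumberTree
    simulated_cost: int


def random_topology(k: int, rng: np.random.Generator) -> CopyNumberTree:
    """Random full binary shape: repeatedly split a uniformly chosen leaf.

    Leaves are then assigned sample labels 1..k by a uniform permutation.
    Profiles and events are left empty; :func:`random_events` fills them.
    """
    if k < 2:
        raise ValueError("need at least two leaves")
    tree = CopyNumberTree(root=0, profiles={0: ()}, children={0: ()})
    nxt = 1
    leaves = [0]
    while len(leaves) < k:
        pick = leaves.pop(int(rng.integers(len(leaves))))
        kids = (nxt, nxt + 1)
        nxt += 2
        tree.children[pick] = kids
        for c in kids:
            tree.profiles[c] = ()
            tree.children[c] = ()
            leaves.append(c)
    perm = rng.permutation(k)
    tree.leaf_labels = {v: f"s{perm[t] + 1}" for t, v in enumerate(sorted(leaves))}
    return tree


def random_events(shape: CopyNumberTree, config: SimulationConfig,
                  rng: np.random.Generator) -> CopyNumberTree:
    """Label every edge with random events and propagate profiles from the root."""
    n = config.n
    shape.profiles[shape.root] = tuple([2] * n)
    order = [shape.root]
    i = 0
    while i < len(order):
        order.extend(shape.children.get(order[i], ()))
        i += 1
    for u in order:
        for v in shape.children.get(u, ()):
            count = int(rng.integers(1, config.m + 1))
            seq = []
            pairs = n * (n + 1) // 2
            for _ in range(count):
                # uniform over the n(n+1)/2 intervals with s <= t
                r = int(rng.integers(pairs))
                s = 1
                while r >= n - s + 1:
                    r -= n - s + 1
                    s += 1
                t = s + r
                b = 1 if rng.random() < config.rho else -1
                seq.append(Event(s, t, b))
            shape.events[(u, v)] = tuple(seq)
            shape.profiles[v] = apply_sequence(shape.profiles[u], seq)
    return shape


def generate_instance(config: SimulationConfig) -> SimulatedInstance:
    """Draw one seeded instance: leaves' profiles, derived cap e, truth tree."""
    rng = np.random.default_rng(config.seed)
    tree = random_events(random_topology(config.k, rng), config, rng)
    leaves = sorted(tree.leaves(), key=lambda v: int(tree.leaf_labels[v][1:]))
    profiles = tuple(tree.profiles[v] for v in leaves)
    e = max(2, max(max(p) for p in profiles))
    instance = CntInstance(profiles, e, ids=tuple(tree.leaf_labels[v] for v in leaves))
    cost = sum(sequence_cost(seq) for seq in tree.events.values())
    return SimulatedInstance(config, instance, tree, cost)
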