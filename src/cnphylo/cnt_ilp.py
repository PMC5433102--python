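"""The copy-number tree problem as an integer linear program.

Given k observed profiles and a copy-number cap e, find a minimum-cost
rooted full binary tree whose leaves carry the observed profiles, whose
internal vertices carry inferred ancestral profiles bounded by e, and whose
root is diploid. The search is over spanning trees of a supergraph G on
2k - 1 vertices (vertex 1 the root, vertices k..2k-1 the leaves, arcs
(i, j) for every internal i < j) that contains every full binary tree with k
leaves as a spanning tree.

Per arc and position the model carries the total deletion cost d and
amplification cost a covering that position (deletions are applied before
amplifications, which is sufficient for optimality), links them to the
endpoint labels by a four-way case analysis on zero/nonzero values, and
charges only the events that *start* at each position, so that an event
spanning several positions is paid once. The backend is the HiGHS
mixed-integer solver via :func:`scipy.optimize.milp`.

To cover histories in which the diploid root has a single descendant
lineage, :func:`solve_cnt` additionally solves the instance augmented with
an all-diploid extra leaf and returns the cheaper of the two trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .core import (
    CopyNumberTree,
    Event,
    EventSequence,
    Profile,
    apply_sequence,
    as_profile,
    tree_cost,
    validate_tree,
)
from .distance import INF, distance

__all__ = [
    "CntInstance",
    "SuperGraph",
    "CntModel",
    "CntSolution",
    "DecodingError",
    "build_graph",
    "build_model",
    "solve_model",
    "reconstruct_events",
    "solve_cnt",
    "cnt_brute_oracle",
]


class DecodingError(RuntimeError):
    """Raised when a solver assignment cannot be decoded into a valid tree."""


@dataclass(frozen=True)
class CntInstance:
    """k copy-number profiles of equal length plus the copy-number cap e."""

    profiles: tuple[Profile, ...]
    e: int
    ids: tuple[str, ...] | None = None

    def __post_init__(self):
        profiles = tuple(as_profile(p) for p in self.profiles)
        object.__setattr__(self, "profiles", profiles)
        if len(profiles) < 2:
            raise ValueError("need at least two profiles")
        n = len(profiles[0])
        if any(len(p) != n for p in profiles):
            raise ValueError("profiles must have equal length")
        if self.e < 2:
            raise ValueError("copy-number cap e must be at least 2 (diploid root)")
        if any(max(p) > self.e for p in profiles):
            raise ValueError("an input profile exceeds the cap e")
        if self.ids is not None and len(self.ids) != len(profiles):
            raise ValueError("ids must match profiles")

    @property
    def k(self) -> int:
        return len(self.profiles)

    @property
    def n(self) -> int:
        return len(self.profiles[0])

    def sample_ids(self) -> tuple[str, ...]:
        return self.ids if self.ids is not None else tuple(
            f"s{i + 1}" for i in range(self.k)
        )

    def augmented(self) -> "CntInstance":
        """The same instance with an extra all-diploid leaf appended."""
        extra = tuple([2] * self.n)
        ids = self.sample_ids() + ("diploid_aux",)
        return CntInstance(self.profiles + (extra,), self.e, ids)


@dataclass(frozen=True)
class SuperGraph:
    """Directed acyclic supergraph containing every full binary tree on k leaves."""

    k: int
    arcs: tuple[tuple[int, int], ...]

    @property
    def n_vertices(self) -> int:
        return 2 * self.k - 1

    def internal(self) -> range:
        return range(1, self.k)

    def leaves(self) -> range:
        return range(self.k, 2 * self.k)

    def in_neighbors(self, j: int) -> list[int]:
        return [i for (i, jj) in self.arcs if jj == j]

    def out_neighbors(self, i: int) -> list[int]:
        return [j for (ii, j) in self.arcs if ii == i]


def build_graph(k: int) -> SuperGraph:
    """Vertices 1..2k-1 (1 = root, k..2k-1 = leaves); arcs (i, j) for internal i < j."""
    if k < 2:
        raise ValueError("need at least two leaves")
    arcs = tuple((i, j) for i in range(1, k) for j in range(i + 1, 2 * k))
    return SuperGraph(k, arcs)


@dataclass
class CntModel:
    """Sparse MILP: objective, bounds, integrality, constraints, variable index."""

    instance: CntInstance
    graph: SuperGraph
    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    constraints: LinearConstraint
    index: dict[tuple, int] = field(repr=False)

    @property
    def n_variables(self) -> int:
        return self.c.size


def build_model(instance: CntInstance) -> CntModel:
    """Assemble the MILP for one instance.

    Variables (all per-position quantities indexed by arc (i, j) and
    position s, 1-based):

    * ``x[i,j]``      — arc selected in the tree (binary);
    * ``y[i,s]``      — copy number at vertex i (0..e; fixed for root/leaves);
    * ``z[i,s,q]``    — binary expansion bits of ``y[i,s]``;
    * ``yb[i,s]``     — indicator that ``y[i,s]`` is nonzero;
    * ``a/d[i,j,s]``  — amplification / deletion cost covering position s;
    * ``ab/db[i,j,s]``— amplifications / deletions *starting* at s;
    * ``w[i,j,s]``    — cost charged to the objective (>= ab+db on selected arcs).

    The case constraints are emitted for every arc of the supergraph;
    unselected arcs always admit a zero-cost completion.
    """
    g = build_graph(instance.k)
    k, n, e = instance.k, instance.n, instance.e
    Q = math.floor(math.log2(e)) + 2  # bits q = 0 .. floor(log2 e) + 1

    index: dict[tuple, int] = {}

    def add(*key) -> int:
        index[key] = len(index)
        return index[key]

    for (i, j) in g.arcs:
        add("x", i, j)
    for i in range(1, 2 * k):
        for s in range(1, n + 1):
            add("y", i, s)
            add("yb", i, s)
            for q in range(Q):
                add("z", i, s, q)
    for (i, j) in g.arcs:
        for s in range(1, n + 1):
            for name in ("a", "d", "ab", "db", "w"):
                add(name, i, j, s)

    nv = len(index)
    c = np.zeros(nv)
    lb = np.zeros(nv)
    ub = np.empty(nv)
    integrality = np.ones(nv)
    for key, ix in index.items():
        name = key[0]
        if name in ("x", "yb", "z"):
            ub[ix] = 1
        elif name == "w":
            ub[ix] = np.inf
            integrality[ix] = 0
            c[ix] = 1.0
        else:
            ub[ix] = e

    # Fixed labels: diploid root, observed leaves (with consistent indicators).
    for s in range(1, n + 1):
        lb[index["y", 1, s]] = ub[index["y", 1, s]] = 2
        lb[index["yb", 1, s]] = 1
        for i in range(k, 2 * k):
            val = instance.profiles[i - k][s - 1]
            lb[index["y", i, s]] = ub[index["y", i, s]] = val
            lb[index["yb", i, s]] = ub[index["yb", i, s]] = 1 if val else 0

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    row = 0

    def emit(terms: list[tuple[int, float]], lo_v: float, hi_v: float):
        nonlocal row
        for ix, v in terms:
            rows.append(row)
            cols.append(ix)
            vals.append(v)
        lo.append(lo_v)
        hi.append(hi_v)
        row += 1

    # Spanning-tree degree constraints: in-degree 1, internal out-degree 2.
    for j in range(2, 2 * k):
        emit([(index["x", i, j], 1.0) for i in g.in_neighbors(j)], 1, 1)
    for i in range(1, k):
        emit([(index["x", i, j], 1.0) for j in g.out_neighbors(i)], 2, 2)

    # Nonzero indicators through the binary expansion of each label.
    for i in range(1, 2 * k):
        for s in range(1, n + 1):
            terms = [(index["y", i, s], 1.0)]
            terms += [(index["z", i, s, q], -float(2 ** q)) for q in range(Q)]
            emit(terms, 0, 0)
            terms = [(index["yb", i, s], 1.0)]
            terms += [(index["z", i, s, q], -1.0) for q in range(Q)]
            emit(terms, -np.inf, 0)
            for q in range(Q):
                emit([(index["z", i, s, q], 1.0), (index["yb", i, s], -1.0)], -np.inf, 0)

    # Case analysis linking endpoint labels and per-position event costs.
    for (i, j) in g.arcs:
        for s in range(1, n + 1):
            y_i, y_j = index["y", i, s], index["y", j, s]
            yb_i, yb_j = index["yb", i, s], index["yb", j, s]
            a = index["a", i, j, s]
            d = index["d", i, j, s]
            # both nonzero: y_j = y_i - d + a, with d <= y_i - 1
            emit([(y_j, 1.0), (y_i, -1.0), (d, 1.0), (a, -1.0),
                  (yb_i, 2.0 * e), (yb_j, 2.0 * e)], -np.inf, 4.0 * e)
            emit([(y_i, 1.0), (y_j, -1.0), (d, -1.0), (a, 1.0),
                  (yb_i, 2.0 * e), (yb_j, 2.0 * e)], -np.inf, 4.0 * e)
            emit([(d, 1.0), (y_i, -1.0), (yb_i, e + 1.0), (yb_j, e + 1.0)],
                 -np.inf, 2.0 * (e + 1) - 1)
            # parent nonzero, child zero: d >= y_i
            emit([(y_i, 1.0), (d, -1.0), (yb_i, float(e)), (yb_j, -float(e))],
                 -np.inf, float(e))
            # lost positions stay lost along selected arcs
            emit([(index["x", i, j], 1.0), (yb_j, 1.0), (yb_i, -1.0)], -np.inf, 1)

    # Events starting at position s; the objective charges only selected arcs.
    for (i, j) in g.arcs:
        x = index["x", i, j]
        for s in range(1, n + 1):
            for cover, start in (("a", "ab"), ("d", "db")):
                terms = [(index[start, i, j, s], 1.0), (index[cover, i, j, s], -1.0)]
                if s > 1:
                    terms.append((index[cover, i, j, s - 1], 1.0))
                emit(terms, 0, np.inf)
            emit([(index["w", i, j, s], 1.0), (index["ab", i, j, s], -1.0),
                  (index["db", i, j, s], -1.0), (x, -2.0 * e)], -2.0 * e, np.inf)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(row, nv))
    constraints = LinearConstraint(A, np.array(lo), np.array(hi))
    return CntModel(instance, g, c, lb, ub, integrality, constraints, index)


@dataclass
class SolveResult:
    """Raw MILP outcome: variable values keyed like the model index."""

    values: dict[tuple, float]
    objective: float
    status: str  # "optimal" | "feasible" | "infeasible"
    bound: float


def solve_model(model: CntModel, time_limit: float | None = 600.0,
                solver: str = "highs", seed: int | None = None,
                mip_gap: float = 1e-6) -> SolveResult:
    """Solve the MILP with HiGHS; returns the assignment, status and dual bound.

    ``seed`` is accepted for interface uniformity; the backend is
    deterministic so it has no effect.
    """
    if solver != "highs":
        raise ValueError(f"unknown solver {solver!r}; available: 'highs'")
    if time_limit is not None and time_limit <= 0:
        raise ValueError("time limit must be positive")
    options = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=model.c,
        constraints=model.constraints,
        integrality=model.integrality,
        bounds=(model.lb, model.ub),
        options=options,
    )
    if res.x is None:
        return SolveResult({}, math.inf, "infeasible", math.inf)
    status = "optimal" if res.status == 0 else "feasible"
    values = {key: float(res.x[ix]) for key, ix in model.index.items()}
    bound = float(res.mip_dual_bound) if res.mip_dual_bound is not None else -math.inf
    return SolveResult(values, float(res.fun), status, bound)


def reconstruct_events(parent: Sequence[int], child: Sequence[int],
                       amp_track: Sequence[int], del_track: Sequence[int]) -> EventSequence:
    """Turn per-position amplification/deletion cost tracks into unit events.

    Deletions first: for each coverage level, every maximal run of positions
    whose deletion track reaches that level becomes one unit deletion; then
    likewise for amplifications. The total event count is the sum of positive
    track increments. Raises :class:`DecodingError` if applying the result to
    the parent does not reproduce the child.
    """
    parent, child = as_profile(parent), as_profile(child)
    events: list[Event] = []
    for track, b in ((del_track, -1), (amp_track, +1)):
        top = max(track, default=0)
        for level in range(1, top + 1):
            s = None
            for pos, cov in enumerate(track, start=1):
                if cov >= level and s is None:
                    s = pos
                elif cov < level and s is not None:
                    events.append(Event(s, pos - 1, b))
                    s = None
            if s is not None:
                events.append(Event(s, len(parent), b))
    got = apply_sequence(parent, events)
    if got != child:
        bad = next(i for i in range(len(child)) if got[i] != child[i])
        raise DecodingError(
            f"tracks do not transform parent into child at position {bad + 1}: "
            f"expected {child[bad]}, got {got[bad]}"
        )
    return tuple(events)


def _decode(model: CntModel, result: SolveResult) -> CopyNumberTree:
    """Build a CopyNumberTree from a feasible assignment."""
    inst, g = model.instance, model.graph
    k, n = inst.k, inst.n
    vals = result.values
    selected = [(i, j) for (i, j) in g.arcs if vals["x", i, j] > 0.5]
    profiles = {
        i: tuple(int(round(vals["y", i, s])) for s in range(1, n + 1))
        for i in range(1, 2 * k)
    }
    children: dict[int, tuple[int, ...]] = {i: () for i in range(1, 2 * k)}
    for (i, j) in selected:
        children[i] = children[i] + (j,)
    events = {}
    for (i, j) in selected:
        amp = [int(round(vals["a", i, j, s])) for s in range(1, n + 1)]
        dele = [int(round(vals["d", i, j, s])) for s in range(1, n + 1)]
        try:
            events[(i, j)] = reconstruct_events(profiles[i], profiles[j], amp, dele)
        except DecodingError as exc:
            raise DecodingError(f"arc ({i},{j}): {exc}") from exc
    ids = inst.sample_ids()
    leaf_labels = {k + t: ids[t] for t in range(k)}
    aux = {k + t for t in range(k) if ids[t] == "diploid_aux"}
    tree = CopyNumberTree(
        root=1, profiles=profiles, children=children, events=events,
        leaf_labels=leaf_labels, auxiliary_leaves=aux,
    )
    errs = validate_tree(tree, inst)
    if errs:
        raise DecodingError("; ".join(errs))
    return tree


@dataclass
class CntSolution:
    """Decoded tree, its cost, solve status and lower bound."""

    tree: CopyNumberTree
    cost: int
    status: str
    bound: float
    used_augmented: bool


def solve_cnt(instance: CntInstance, time_limit: float | None = 600.0,
              solver: str = "highs", seed: int | None = None) -> CntSolution:
    """Solve the plain and diploid-augmented instances; return the cheaper tree.

    The augmentation covers optimal histories where the diploid root has one
    descendant lineage: the extra all-2's leaf rides on a zero-cost edge. Its
    leaf is flagged auxiliary in the decoded tree so evaluation can drop it.
    """
    plain = build_model(instance)
    res_p = solve_model(plain, time_limit=time_limit, solver=solver, seed=seed)
    aug = build_model(instance.augmented())
    res_a = solve_model(aug, time_limit=time_limit, solver=solver, seed=seed)

    cand = []
    if res_p.status != "infeasible":
        cand.append((res_p.objective, 0, plain, res_p))
    if res_a.status != "infeasible":
        cand.append((res_a.objective, 1, aug, res_a))
    if not cand:
        raise DecodingError("both instance variants infeasible")
    cand.sort(key=lambda t: (round(t[0], 6), t[1]))
    obj, which, model, res = cand[0]
    tree = _decode(model, res)
    cost = tree_cost(tree)
    # The augmented optimum never exceeds the plain one (append the diploid
    # leaf under a fresh root at zero cost), so a proven-optimal augmented
    # solve proves the combined answer; a winning plain solve additionally
    # needs the augmented dual bound to reach it.
    if which == 1:
        optimal = res.status == "optimal"
    else:
        optimal = res.status == "optimal" and (
            res_a.status == "optimal" or res_a.bound >= obj - 1e-6
        )
    return CntSolution(
        tree=tree,
        cost=cost,
        status="optimal" if optimal else "feasible",
        bound=min(r.bound for (_, _, _, r) in cand),
        used_augmented=bool(which),
    )


def _all_topologies(k: int):
    """All rooted full binary leaf-labeled shapes on leaves 0..k-1 ((2k-3)!! trees)."""

    def insert(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            left, right = t
            for nl in insert(left, leaf):
                yield (nl, right)
            for nr in insert(right, leaf):
                yield (left, nr)

    trees = [(0, 1)]
    for leaf in range(2, k):
        trees = [nt for t in trees for nt in insert(t, leaf)]
    return trees


def _min_labeling_cost(shape, dist: np.ndarray, leaf_state: list[int],
                       root_state: int) -> int:
    """Exact small-parsimony cost of one shape over a bounded profile alphabet.

    Bottom-up over vertices: for every candidate parent state, add for each
    child the cheapest (directed distance + child subtree) state.
    """
    A = dist.shape[0]

    def vec(t) -> np.ndarray:
        if not isinstance(t, tuple):
            out = np.full(A, INF, dtype=np.int64)
            out[leaf_state[t]] = 0
            return out
        left, right = t
        vl, vr = vec(left), vec(right)
        return (
            np.minimum(dist + vl[None, :], INF).min(axis=1)
            + np.minimum(dist + vr[None, :], INF).min(axis=1)
        )

    return int(min(vec(shape)[root_state], INF))


def cnt_brute_oracle(instance: CntInstance, max_leaves: int = 5,
                     max_alphabet: int = 256) -> int:
    """Exact minimum tree cost by exhaustive topology + labeling search.

    Enumerates every rooted full binary leaf-labeled topology and, per
    topology, the exact optimal internal labeling over all profiles with
    entries in 0..e (root fixed diploid) by dynamic programming on the tree.
    Both the plain and the diploid-augmented variants are searched and the
    minimum returned. Independent of the ILP.
    """
    best = INF
    for inst in (instance, instance.augmented()):
        k, n, e = inst.k, inst.n, inst.e
        if k > max_leaves:
            raise ValueError(f"too many leaves ({k}) for brute force")
        alphabet = list(product(range(e + 1), repeat=n))
        if len(alphabet) > max_alphabet:
            raise ValueError("profile alphabet too large for brute force")
        idx = {p: i for i, p in enumerate(alphabet)}
        A = len(alphabet)
        dist = np.empty((A, A), dtype=np.int64)
        for ip, p in enumerate(alphabet):
            for iq, q in enumerate(alphabet):
                dist[ip, iq] = distance(p, q)
        leaf_state = [idx[as_profile(p)] for p in inst.profiles]
        root_state = idx[tuple([2] * n)]
        for shape in _all_topologies(k):
            best = min(best, _min_labeling_cost(shape, dist, leaf_state, root_state))
    return best
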