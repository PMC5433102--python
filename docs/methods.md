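# Methods

## Model

A chromosome is divided into `n` contiguous positions; the state of a clone
is its *copy-number profile* `y = (y_1, …, y_n)`, a vector of non-negative
integers (the diploid, unmutated state is all 2's). Evolution proceeds by
segmental *events* `(s, t, b)`: every currently nonzero entry in the
1-based inclusive window `[s, t]` becomes `max(y_l + b, 0)`. Amplifications
have `b > 0`, deletions `b < 0`, and the cost of an event is `|b|`. Two
consequences shape everything downstream:

* **Zero absorption.** A position that reaches copy number 0 is frozen
  forever; consequently the one-directional distance `dist(p → q)` (minimum
  total cost of a sequence turning p into q) is asymmetric and is infinite
  exactly when some position is zero in p but nonzero in q.
* **Sortedness.** Any sequence can be replaced by one of no higher cost in
  which all deletions precede all amplifications, and events with `|b| > 1`
  can be split into unit events of the same total cost. All solvers
  therefore work with sorted unit-event sequences.

A *copy-number tree* is a rooted full binary tree whose vertices carry
profiles, whose root is diploid, and whose edges carry ordered event
sequences transforming the parent profile into the child profile; its cost
is the summed edge cost. The two problems solved here:

* **Median (triplet) problem** — given profiles u, v, find a parent m and
  sequences to u and to v of minimum total cost `Δ(u, v)`. Always finite
  and symmetric.
* **Tree problem** — given k leaf profiles and a copy-number cap `e ≥ 2`,
  find a minimum-cost copy-number tree whose k leaves carry the given
  profiles and all of whose vertex entries are at most `e`.

## Pairwise distance

`G[i, d, a]` is the minimum cost of a sequence carrying the length-`i`
prefix of p to that of q with exactly `d` deletion units and `a`
amplification units covering position `i`; both budgets are bounded by the
maximum input copy number `B` (larger budgets never help). Feasibility at a
position is pure arithmetic: if `q_i > 0` then `d < p_i` and
`q_i = p_i − d + a`; if `q_i = 0` then `d ≥ p_i`. The first position costs
`d + a`; each later position pays only the budget increments
`max(d − d′, 0) + max(a − a′, 0)` over the best predecessor `(d′, a′)`,
because an event covering position `i` extends backwards over position
`i − 1` for free. The answer is the minimum over the last column.

The inner minimum has the form `h(x) = min_{x′} g(x′) + max(x − x′, 0)`,
which equals `min(suffix-min g, x + prefix-min (g − x′))` and is computed
by two linear scans per axis; the table values are identical to evaluating
the displayed minimum directly, just cheaper, and the whole table is a few
numpy scans per position. Infinity is a sentinel integer (`10^9`) strictly
larger than any feasible cost (at most `2nB`), so minimum-folds need no
special-casing.

An independent check, used throughout the tests, is a breadth-first search
in the graph of all profiles with entries `0..cap` whose arcs are all unit
events: exhaustive agreement is verified for every profile pair with
`n ≤ 3` and entries `≤ 3`, with `cap` equal to the largest input entry
(amplifying beyond the larger of source and target never helps at unit
granularity; the sweep validates this empirically rather than assuming it).

## Median dynamic program

The table `L[i, m, d_u, a_u, d_v, a_v]` stores the minimum summed cost of
partial solutions over the first `i` positions in which the parent's value
at `i` is `m` and the four per-position budgets (deletions/amplifications
toward u and toward v) are as indexed; all five indices are bounded by `B`,
justified by the existence of an optimal parent with entries in `1..B`
(jointly-zero positions are stripped first and restored afterwards). The
per-position feasibility conditions are the pairwise ones applied to both
arms, the first position costs the sum of its four budgets, and transitions
pay the four budget increments over the best predecessor state, with the
parent value additionally capped by an optional `e` (default: no cap
beyond `B`). The same separable-scan evaluation as the pairwise table is
used, preceded by a minimum over the predecessor parent value.

Two implementations cross-check each other:

* the **full-table** variant keeps all `n (B+1)^5` entries so the optimal
  parent and budget tracks can be traced back (ties broken toward the
  lexicographically smallest coordinate vector, making output
  deterministic);
* the **compressed** variant exploits that when `u_i > 0` the
  amplification budget is determined (`a_u = u_i − m + d_u`), storing only
  consistent coordinates, and restricts predecessor enumeration: when
  `u_{i−1} > 0` the predecessor's `a_u′` is determined the same way; when
  `u_{i−1} = 0` it suffices to consider `d_u′ = max(d_u, m′)` and
  `a_u′ = a_u`, because events covering position `i` can be extended over
  the lost position `i − 1` at no cost, and events touching only `i − 1`
  can be shrunk. Symmetrically for v.

Event sequences are recovered from the traced budget tracks by *skyline
decomposition*: for each coverage level, every maximal run of positions
whose track reaches that level becomes one unit event; deletions are
emitted before amplifications. The per-position arithmetic guarantees the
result transforms the parent into each child, which is re-checked
mechanically on every solve.

Exhaustive equivalence of both variants with a brute-force search (every
candidate parent priced by the breadth-first oracle) is verified for all
pairs with `n ≤ 2`, entries `≤ 3`, and on random larger instances.

## Tree MILP

The solver searches spanning trees of a supergraph `G` on `2k − 1`
vertices — vertex 1 the diploid root, vertices `k..2k−1` the leaves, arcs
`(i, j)` for every internal `i < j` — which contains every full binary tree
with `k` leaves. Binary arc variables `x` with in-degree 1 (non-root) and
out-degree 2 (internal) select the tree; integer label variables
`y ∈ {0..e}` are fixed at the root and leaves; indicator variables `ȳ`
(`ȳ = 1` iff `y ≠ 0`) are linked to `y` through a binary expansion
`y = Σ 2^q z_q`, `q = 0..⌊log₂ e⌋ + 1`. (The expansion can represent values
above `e`; the explicit domain `y ≤ e` closes that gap.)

Per arc and position, integer variables `d, a ∈ {0..e}` carry the deletion
and amplification cost covering the position. Their consistency with the
endpoint labels is a four-case analysis on zero/nonzero endpoint values,
enforced with big-M constraints driven by the indicators: both nonzero
forces `y_child + d = y_parent + a` with `d < y_parent`; parent nonzero and
child zero forces `d ≥ y_parent`; parent zero and child nonzero is
forbidden along selected arcs; both zero is unconstrained. Start variables
`ā ≥ a_s − a_{s−1}`, `đ ≥ d_s − d_{s−1}` (with position-0 boundary 0)
charge each event only where it starts, and the objective
`min Σ w` with `w ≥ ā + đ − 2e(1 − x)` zeroes the charge on unselected
arcs. The case constraints are emitted for every supergraph arc, selected
or not; unselected arcs always admit a zero-cost completion. No
symmetry-breaking constraints are added beyond the `i < j` arc orientation
inherent in the supergraph.

The backend is the HiGHS mixed-integer solver through
`scipy.optimize.milp`, with a configurable time limit (default 600 s) and
the dual bound reported when optimality is not proven. HiGHS is
deterministic, so a seed option exists only for interface uniformity.

Decoding reads the selected arcs, rounds the labels, and rebuilds each
edge's sorted unit-event sequence from the `(d, a)` tracks by the same
skyline decomposition as the median traceback; the decoded tree is passed
through a full structural validator (full binary, diploid root, label cap,
edge consistency, leaf identity) before being returned.

Because the problem fixes the root's out-degree at 2 but an optimal
history may hang everything off a single root lineage, each solve is run
twice: once as given and once with an extra all-diploid leaf appended,
returning the cheaper tree (ties prefer the plain instance). The appended
leaf can always ride at zero cost under a fresh root above the plain
optimum, so the augmented optimum never exceeds the plain one; hence a
proven-optimal augmented solve proves the combined answer, while a winning
plain solve also needs the augmented dual bound to reach its objective.
The auxiliary leaf is flagged and dropped before topology comparison.

An exhaustive oracle cross-checks the MILP at desk scale: every rooted
full binary leaf-labeled topology (`(2k−3)!!` of them) combined with an
exact dynamic program over the bounded profile alphabet `{0..e}^n` for the
internal labels (directed edge costs from the pairwise solver, root fixed
diploid), again over both the plain and augmented variants.

## Simulator

The generator reproduces the conditions of the simulation study the
package's defaults are calibrated to: a random full binary topology with
`k` leaves grown by repeatedly splitting a uniformly chosen leaf, leaf
labels assigned by a uniform permutation; each edge labeled with `d`
events, `d` uniform on `{1..m}`; each event's interval drawn uniformly
from the `n(n+1)/2` pairs `s ≤ t` and its sign positive with probability
`ρ`; profiles propagated from the diploid root in order. The instance's
cap `e` is the maximum leaf entry, floored at 2 so the root is
representable. All randomness flows through one `numpy` generator seeded
from the configuration.

Two deliberate consequences: events drawn entirely over lost positions
still count toward the recorded simulated cost, so the inferred parsimony
cost can undercut the simulated cost; and internal ancestral profiles may
exceed the leaf-derived `e`, in which case the generating tree itself is
not feasible for the solver — the solver can still find an equal-or-cheaper
tree, and the cost-recovery readout tolerates this by construction.

The generator emulates clean integer profiles only: no read-coverage
noise, no fractional copy numbers from impure samples, no multi-chromosome
genomes, no allele phasing, no clone mixtures. Results on simulated
instances therefore speak to the solvers' correctness and to the parsimony
assumption, not to robustness against measurement error in real data.

## Topology comparison

Inferred and generating trees are compared as *rooted* topologies, which
is the natural reading for histories rooted at a fixed diploid ancestor:
each internal vertex below the root contributes the set of leaf labels
under it, and the distance is the size of the symmetric difference of the
two clade sets divided by the total number of nontrivial clades in both
trees — 0 for identical topologies, 1 for disjoint clade sets; for two
full binary trees on `k` leaves the denominator is `2(k − 2)`. An unrooted
variant over bipartitions is available (`rooted=False`, `--unrooted`) for
sensitivity checks and is cross-checked against dendropy in the tests.
Auxiliary diploid leaves are removed and their attachment vertices
suppressed before comparison.

## Parsimony embedding

Binary-vector maximum parsimony (full binary tree, leaves given, root
all-0, Hamming edge costs) embeds into the tree problem with cap `e = 2`:
value 1 maps to copy number 1, value 0 to 2, and the `n` true positions
are separated by *walls* — alternating `(2, 1)` buffers of length `nk`
whose one-off initialization costs `W = (n − 1)nk/2` and whose role is to
prevent a single event from usefully spanning two true positions. An extra
all-diploid profile lets the walls initialize on one shared edge below the
root. Any parsimony tree of cost `h` maps onto a copy-number tree of cost
exactly `h + W` (each bit flip becomes a unit event at one true position),
so the encoded optimum is at most `h + W`; the tests verify this bound on
every tiny instance.

Exact equality, however, is an asymptotic property, not a small-`n` one,
and the package treats it that way. At `n ≤ 2` two effects let the encoded
optimum drop below `h + W`: a deletion run may cross a wall boundary
together with an adjacent true position, sharing wall-initialization cost
with a flip; and the subtree hanging below the shared wall-initialization
edge may root at any encoded vector, whereas the parsimony problem pins
its root at all-0 and pays the corresponding flips twice. A computed sweep
over all 20 two-vector instances with `n ∈ {1, 2}` finds 12 exact
agreements and 8 instances where the tree optimum is strictly smaller
(e.g. two identical `(1,)` leaves: tree cost 1 versus `h + W = 2`). The
walls dominate once `n` is moderately large (the accounting used in the
hardness argument assumes `n ≥ 4`), which is exactly the regime the gadget
exists for; the tests pin the constructive bound everywhere and exact
equality on instances where walls bind.

## Problem sizes and numerical choices

* Exhaustive sweeps: distances on all pairs with `n ≤ 3`, entries `≤ 3`;
  medians on all pairs with `n ≤ 2`, entries `≤ 3`; tree solves against
  the enumeration oracle on 30 seeded instances with `k ∈ {2, 3}`,
  `n ≤ 3`, `e = 3`. Randomized median sweeps go up to `n = 50`, `B = 6`.
* Batch studies (also rerun by `scripts/acceptance.py`): the topology
  recovery study uses `k = 4`, `n ∈ {20, 30, 40}`, `m ∈ {1, 2, 3}`,
  `ρ ∈ {0.2, 0.4}`, three instances per combination; the cost-recovery
  study uses two replicates of the `k = 4`, `n ∈ {10, 20}` grid plus a
  time-capped `k = 6`, `n = 10` attempt. Per-solve MILP time limits are
  90–120 s and each batch carries a wall-clock soft cap; with the
  open-source single-thread backend, `k = 4` instances prove optimality in
  seconds while `k = 6` instances often cannot within minutes, so
  summaries are taken over proven-optimal solves (the commercial-solver
  study this mirrors gave each instance five hours on a cluster node and
  still had timeouts at `k = 8`).
* Integer infinity is `10^9`; all DP arithmetic is `int64`; MILP label
  values are rounded at decode time and every decoded tree re-validated
  exactly in integer arithmetic. DP ties break lexicographically; MILP
  ties among optimal trees are solver-dependent, so tests compare costs
  and validity, never one specific optimal tree.

## Known limitations

Single chromosome only; integer profiles only; no phasing, no clone-mixture
deconvolution, no missing data. The median traceback uses the full
(uncompressed) table, so its memory is `O(nB^5)` — ample for `B ≤ 8` but
the compressed cost-only variant should be preferred for large `B`.
Proven-optimal tree solves at `k ≥ 6` require either generous time budgets
or a commercial MILP backend.
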