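# cnphylo

Maximum-parsimony evolution of **copy-number profiles** — the integer
vectors of per-position copy counts that describe tumor clones after
segmental amplifications and deletions. Given profiles measured from bulk
or single-cell samples, `cnphylo` answers two questions exactly:

* **Median (CN3):** for two profiles `u`, `v`, find a parental profile `m`
  and event sequences minimizing `δ(m→u) + δ(m→v)`.
* **Phylogeny (CNT):** for `k` profiles and a copy-number cap `e`, find a
  minimum-cost rooted full binary tree whose leaves carry the profiles,
  whose root is diploid (all 2's), and whose edges are labeled by the
  segmental events that transform parent into child.

The event model: an event `(s, t, b)` adds `b` (clamped below at 0) to all
currently nonzero entries in positions `s..t` and costs `|b|`; a position
at copy number 0 is lost forever. The resulting edge distance
`δ(p→q)` is asymmetric and possibly infinite. The median is solved by a
dynamic program over per-position amplification/deletion budgets bounded
by the maximum input copy number `B` (a full-table variant with traceback
and a budget-compressed cost-only variant); the phylogeny is solved as an
integer linear program over a supergraph containing every full binary tree
on `k` leaves, using the HiGHS solver. Both come with independent
brute-force oracles, a ground-truthed instance simulator, a normalized
(rooted) Robinson–Foulds topology metric, and an executable embedding of
binary maximum parsimony used as a cross-problem correctness check. See
`docs/methods.md` for the model, algorithms and design choices.

## Worked example

Simulate a 4-leaf instance (8 positions, up to 2 events per edge,
30% amplifications), infer the tree, and compare topologies:

```sh
$ cnphylo simulate --k 4 --n 8 --m 2 --rho 0.3 --seed 11 --out-prefix sim
simulated_cost  12
$ cnphylo cnt --profiles sim.profiles.tsv --e 3 --time-limit 120 --out-prefix fit
cost    10
status  optimal
$ cnphylo evaluate --truth sim.truth.nwk --inferred fit.nwk
0.0
```

The simulator drew events of total cost 12, but the proven-optimal tree
explains the same leaves with cost 10 — parsimony may legitimately undercut
the simulation because drawn events can overlap or hit already-lost
positions. The normalized Robinson–Foulds distance of 0.0 says the inferred
topology `((s1,s2),(s3,s4))` is exactly the simulated one. The edge list
shows the history (the `diploid_aux` leaf is the zero-cost all-diploid
companion used to allow a single lineage below the root):

```
$ cat fit.edges.tsv
# parent        child   cost
root    v2      1
root    diploid_aux     0
v2      v3      1
v2      v4      1
v3      s1      0
v3      s2      3
v4      s3      2
v4      s4      2
```

Medians and pairwise distances work on the same profile tables:

```sh
$ printf 'u\t2\t0\t3\t1\nv\t1\t2\t0\t1\n' > uv.tsv
$ cnphylo cn3 --profiles uv.tsv --u u --v v --emit-median med
5
$ cat med.median.tsv
median  1       1       1       1
$ cnphylo distance --from u --to v --profiles uv.tsv
INF
```

The best common parent of `u = (2,0,3,1)` and `v = (1,2,0,1)` is
`(1,1,1,1)` at total cost 5, while the one-directional distance `u → v` is
infinite: position 2 is already lost in `u` and can never be regained.

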