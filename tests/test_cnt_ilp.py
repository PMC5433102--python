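import math
import random

import pytest

from cnphylo.core import Event, apply_sequence, sequence_cost, tree_cost, validate_tree
from cnphylo.cnt_ilp import (
    CntInstance,
    DecodingError,
    build_graph,
    build_model,
    cnt_brute_oracle,
    reconstruct_events,
    solve_cnt,
    solve_model,
)
from cnphylo.distance import distance


@pytest.mark.parametrize("k, n_vertices, n_arcs", [(2, 3, 2), (3, 5, 7), (4, 7, 15)])
def test_build_graph_counts(k, n_vertices, n_arcs):
    g = build_graph(k)
    assert g.n_vertices == n_vertices
    assert len(g.arcs) == n_arcs
    assert all(i < j for (i, j) in g.arcs)


def test_build_graph_rejects_single_leaf():
    with pytest.raises(ValueError):
        build_graph(1)


def test_instance_validation():
    with pytest.raises(ValueError):
        CntInstance(((2, 2),), 2)
    with pytest.raises(ValueError):
        CntInstance(((2, 2), (3, 2)), 2)  # entry above cap
    with pytest.raises(ValueError):
        CntInstance(((2,), (2,)), 1)  # cap below diploid


def test_model_variable_counts_k2_n1():
    e = 2
    model = build_model(CntInstance(((2,), (2,)), e))
    names = {}
    for key in model.index:
        names[key[0]] = names.get(key[0], 0) + 1
    q_count = math.floor(math.log2(e)) + 2
    assert names["x"] == 2
    assert names["y"] == 3 and names["yb"] == 3
    assert names["z"] == 3 * q_count
    for name in ("a", "d", "ab", "db", "w"):
        assert names[name] == 2


def test_diploid_instance_costs_zero():
    sol = solve_cnt(CntInstance(((2, 2), (2, 2)), 2))
    assert sol.cost == 0 and sol.status == "optimal"
    assert validate_tree(sol.tree) == []


def test_single_amplification_instance():
    inst = CntInstance(((2, 2), (3, 3)), 3)
    sol = solve_cnt(inst)
    assert sol.cost == 1 and sol.status == "optimal"
    assert cnt_brute_oracle(inst) == 1


def test_augmented_instance_beats_plain():
    # Two haploid leaves: the plain full binary tree needs two deletions, but
    # with the free all-diploid companion leaf a single shared deletion works.
    inst = CntInstance(((1,), (1,)), 2)
    sol = solve_cnt(inst)
    assert sol.cost == 1
    assert sol.used_augmented


def test_objective_bounded_by_star_tree():
    rng = random.Random(3)
    for _ in range(3):
        k, n, e = 3, 3, 3
        profs = tuple(tuple(rng.randint(0, e) for _ in range(n)) for _ in range(k))
        inst = CntInstance(profs, e)
        # diploid-internal tree: every leaf hangs below a diploid vertex
        star = sum(distance(tuple([2] * n), p) for p in profs)
        sol = solve_cnt(inst, time_limit=120)
        assert 0 <= sol.cost <= star


@pytest.mark.parametrize(
    "parent, child, amp, dele, expected_cost",
    [
        ((2, 2), (3, 1), (1, 0), (0, 1), 2),
        ((2, 2), (2, 2), (0, 0), (0, 0), 0),
    ],
)
def test_reconstruct_events_examples(parent, child, amp, dele, expected_cost):
    seq = reconstruct_events(parent, child, amp, dele)
    assert sequence_cost(seq) == expected_cost
    assert apply_sequence(parent, seq) == child
    # deletions precede amplifications
    signs = [ev.b for ev in seq]
    assert signs == sorted(signs)


def test_reconstruct_events_inconsistent_tracks():
    with pytest.raises(DecodingError):
        reconstruct_events((2, 2), (3, 3), (0, 0), (0, 0))


def test_reconstruct_events_round_trip_random():
    rng = random.Random(5)
    for _ in range(80):
        n = rng.randint(1, 6)
        parent = tuple(rng.randint(0, 4) for _ in range(n))
        seq = []
        for _ in range(rng.randint(0, 4)):  # sorted unit events: dels then amps
            s = rng.randint(1, n)
            t = rng.randint(s, n)
            seq.append(Event(s, t, -1))
        for _ in range(rng.randint(0, 4)):
            s = rng.randint(1, n)
            t = rng.randint(s, n)
            seq.append(Event(s, t, +1))
        child = apply_sequence(parent, seq)
        amp = [sum(1 for ev in seq if ev.b > 0 and ev.s <= i <= ev.t) for i in range(1, n + 1)]
        dele = [sum(1 for ev in seq if ev.b < 0 and ev.s <= i <= ev.t) for i in range(1, n + 1)]
        rebuilt = reconstruct_events(parent, child, amp, dele)
        assert apply_sequence(parent, rebuilt) == child
        assert sequence_cost(rebuilt) == sum(
            max(a - ap, 0) + max(d - dp, 0)
            for a, ap, d, dp in zip(amp, [0] + amp[:-1], dele, [0] + dele[:-1])
        )


def test_solver_options_validated():
    model = build_model(CntInstance(((2,), (2,)), 2))
    with pytest.raises(ValueError):
        solve_model(model, solver="cplex")
    with pytest.raises(ValueError):
        solve_model(model, time_limit=0)


def test_solve_matches_brute_oracle_sample():
    rng = random.Random(99)
    done = 0
    while done < 6:
        k = rng.choice([2, 3])
        n = rng.randint(1, 3)
        profs = tuple(tuple(rng.randint(0, 3) for _ in range(n)) for _ in range(k))
        try:
            inst = CntInstance(profs, 3)
        except ValueError:
            continue
        sol = solve_cnt(inst, time_limit=120)
        assert sol.status == "optimal"
        assert sol.cost == cnt_brute_oracle(inst)
        assert sol.cost == tree_cost(sol.tree)
        done += 1
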