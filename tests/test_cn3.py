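import random
from itertools import product

import pytest

from cnphylo.cn3 import (
    cn3_alg1,
    cn3_alg2,
    cn3_brute_oracle,
    cn3_solve,
    cn3_traceback,
    strip_common_zeros,
)
from cnphylo.distance import INF, distance


@pytest.mark.parametrize(
    "u, v, ru, rv, pos_map",
    [
        ((0, 2), (0, 1), (2,), (1,), {1: 2}),
        ((2,), (1,), (2,), (1,), {1: 1}),
        ((0,), (0,), (), (), {}),
    ],
)
def test_strip_common_zeros(u, v, ru, rv, pos_map):
    got_u, got_v, got_map = strip_common_zeros(u, v)
    assert (got_u, got_v, got_map) == (ru, rv, pos_map)


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ((2,), (2,), 0),
        ((2,), (0,), 2),
        ((1,), (3,), 2),
        ((2, 0), (0, 2), 4),
    ],
)
def test_median_cost_examples(u, v, expected):
    ru, rv, _ = strip_common_zeros(u, v)
    assert cn3_alg1(ru, rv)[0] == expected
    assert cn3_alg2(ru, rv) == expected


def test_all_routes_agree_exhaustively():
    """Full DP == compressed DP == brute-force median search at tiny scale."""
    for n in (1, 2):
        for u in product(range(4), repeat=n):
            for v in product(range(4), repeat=n):
                ru, rv, _ = strip_common_zeros(u, v)
                a1 = cn3_alg1(ru, rv)[0]
                assert a1 == cn3_alg2(ru, rv), (u, v)
                assert a1 == cn3_brute_oracle(u, v), (u, v)


def test_algorithms_agree_on_larger_random_instances():
    rng = random.Random(42)
    for n, hi in [(50, 3), (20, 6), (12, 6)]:
        u = tuple(rng.randint(0, hi) for _ in range(n))
        v = tuple(rng.randint(0, hi) for _ in range(n))
        ru, rv, _ = strip_common_zeros(u, v)
        assert cn3_alg1(ru, rv)[0] == cn3_alg2(ru, rv)


def test_traceback_trivial_and_lost_position():
    sol = cn3_solve((2, 2), (2, 2))
    assert sol.median == (2, 2) and sol.seq_to_u == () and sol.cost == 0
    sol = cn3_solve((2,), (0,))
    sol.check((2,), (0,))
    assert sol.cost == 2


def test_traceback_round_trip_random():
    rng = random.Random(7)
    for _ in range(60):
        n = rng.randint(1, 8)
        u = tuple(rng.randint(0, 4) for _ in range(n))
        v = tuple(rng.randint(0, 4) for _ in range(n))
        sol = cn3_solve(u, v)
        sol.check(u, v)  # reproduces u and v at the reported cost, sorted
        ru, rv, _ = strip_common_zeros(u, v)
        assert sol.cost == cn3_alg2(ru, rv)


def test_traceback_deterministic():
    u, v = (2, 0, 3, 1), (1, 2, 0, 1)
    assert cn3_solve(u, v) == cn3_solve(u, v)


def test_symmetry_and_endpoint_bound_randomized():
    """Delta(u,v) = Delta(v,u) <= min over finite one-way distances."""
    rng = random.Random(11)
    for _ in range(25):
        n = rng.randint(1, 50)
        hi = rng.randint(1, 6)
        u = tuple(rng.randint(0, hi) for _ in range(n))
        v = tuple(rng.randint(0, hi) for _ in range(n))
        ru, rv, _ = strip_common_zeros(u, v)
        if not ru:
            continue
        delta = cn3_alg1(ru, rv)[0]
        assert delta == cn3_alg1(rv, ru)[0]
        for a, b in ((u, v), (v, u)):
            d = distance(a, b)
            if d < INF:
                assert delta <= d


def test_optional_cap_restricts_median():
    # u=v=(2,): unconstrained optimum 0 (median (2,)); with the median capped
    # at 1 the only parent is (1,), one amplification per arm.
    assert cn3_alg1((2,), (2,))[0] == 0
    assert cn3_alg1((2,), (2,), e=1)[0] == 2
    assert cn3_alg2((2,), (2,), e=1) == 2
    cost, table = cn3_alg1((1,), (3,))
    assert cn3_traceback(table, (1,), (3,)).cost == cost
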