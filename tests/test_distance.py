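from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnphylo.core import Event, apply_sequence, sequence_cost
from cnphylo.distance import (
    INF,
    distance,
    distance_bfs_oracle,
    distance_table,
    max_copy_bound,
)


@pytest.mark.parametrize(
    "u, v, expected",
    [(((2, 2), (3, 1)), None, 3), (((0,), (0,)), None, 0), (((1, 4, 2), (2, 2, 2)), None, 4)],
)
def test_max_copy_bound(u, v, expected):
    assert max_copy_bound(*u) == expected


def test_max_copy_bound_length_mismatch():
    with pytest.raises(ValueError):
        max_copy_bound((1, 2), (1,))


def test_table_base_cases():
    G = distance_table((2,), (2,))
    assert G[0, 0, 0] == 0
    G = distance_table((2,), (0,))
    assert all(G[0, d, a] >= INF for d in range(2) for a in range(3))
    assert G[0, 2, 0] == 2


@pytest.mark.parametrize(
    "p, q, expected",
    [
        ((2, 2), (2, 2), 0),
        ((0,), (1,), INF),
        ((2,), (0,), 2),
        ((0,), (2,), INF),
        ((2, 2), (3, 1), 2),
        ((2, 1, 2), (1, 2, 1), 3),
    ],
)
def test_distance_examples(p, q, expected):
    assert distance(p, q) == expected


def test_bfs_oracle_basics():
    assert distance_bfs_oracle((2, 1), (2, 1)) == 0
    assert distance_bfs_oracle((2,), (0,), cap=2) == 2
    with pytest.raises(ValueError):
        distance_bfs_oracle((3,) * 12, (2,) * 12)


def test_oracle_equivalence_small():
    """DP equals breadth-first search over unit events, exhaustively at n <= 2."""
    for n in (1, 2):
        for p in product(range(4), repeat=n):
            for q in product(range(4), repeat=n):
                assert distance(p, q) == distance_bfs_oracle(p, q), (p, q)


def test_directed_triangle_inequality_exhaustive():
    vals = list(product(range(4), repeat=2))
    d = {(p, q): distance(p, q) for p in vals for q in vals}
    for p in vals:
        for q in vals:
            for r in vals:
                assert min(d[p, r], INF) <= min(d[p, q] + d[q, r], INF)


@given(
    st.integers(1, 4).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 4), min_size=n, max_size=n).map(tuple),
            st.lists(
                st.tuples(st.integers(1, n), st.integers(1, n), st.integers(-2, 2))
                .filter(lambda e: e[0] <= e[1] and e[2] != 0)
                .map(lambda e: Event(*e)),
                max_size=4,
            ).map(tuple),
        )
    )
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_sorted_sequence_sufficiency(pseq):
    """Whatever a sequence costs, the optimal distance is no larger."""
    p, seq = pseq
    q = apply_sequence(p, seq)
    assert distance(p, q) <= sequence_cost(seq)


def test_finiteness_characterization():
    for n in (1, 2):
        for p in product(range(3), repeat=n):
            for q in product(range(3), repeat=n):
                feasible = all(qi == 0 for pi, qi in zip(p, q) if pi == 0)
                assert (distance(p, q) < INF) == feasible


def test_identity_and_asymmetry():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = tuple(int(x) for x in rng.integers(0, 5, size=rng.integers(1, 6)))
        assert distance(p, p) == 0
    assert distance((2,), (0,)) == 2
    assert distance((0,), (2,)) == INF
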