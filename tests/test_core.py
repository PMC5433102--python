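import pytest
from hypothesis import given, settings, strategies as st

from cnphylo.core import (
    CopyNumberTree,
    Event,
    apply_event,
    apply_sequence,
    as_profile,
    is_sorted,
    sequence_cost,
    to_unit_events,
    tree_cost,
    validate_tree,
)

profiles = st.lists(st.integers(0, 4), min_size=1, max_size=5).map(tuple)


def events_for(n: int):
    return st.tuples(st.integers(1, n), st.integers(1, n), st.integers(-3, 3)).filter(
        lambda e: e[0] <= e[1] and e[2] != 0
    ).map(lambda e: Event(*e))


@pytest.mark.parametrize(
    "profile, event, expected",
    [
        ((2, 2, 2), (1, 2, +1), (3, 3, 2)),
        ((2, 0, 1), (1, 3, -2), (0, 0, 0)),
        ((0, 2), (1, 2, +1), (0, 3)),  # a lost position is never regained
    ],
)
def test_apply_event(profile, event, expected):
    assert apply_event(profile, Event(*event)) == expected


def test_apply_event_out_of_range():
    with pytest.raises(ValueError):
        apply_event((2, 2), Event(1, 3, 1))
    with pytest.raises(ValueError):
        apply_event((2, 2), Event(0, 1, 1))


@pytest.mark.parametrize(
    "profile, seq, expected",
    [
        ((2, 2), (), (2, 2)),
        ((2, 2), ((2, 2, -1), (1, 1, +1)), (3, 1)),
        ((2,), ((1, 1, -2), (1, 1, +5)), (0,)),  # lost position stays lost
    ],
)
def test_apply_sequence(profile, seq, expected):
    assert apply_sequence(profile, [Event(*e) for e in seq]) == expected


@pytest.mark.parametrize(
    "seq, cost",
    [((), 0), (((1, 2, +2), (3, 3, -1)), 3), (((1, 5, -3),), 3)],
)
def test_sequence_cost(seq, cost):
    assert sequence_cost([Event(*e) for e in seq]) == cost


def test_sequence_cost_additive():
    s1 = (Event(1, 2, 2), Event(1, 1, -1))
    s2 = (Event(2, 2, -3),)
    assert sequence_cost(s1 + s2) == sequence_cost(s1) + sequence_cost(s2)


def test_unit_decomposition_examples():
    assert to_unit_events([Event(1, 2, -2)]) == (Event(1, 2, -1), Event(1, 2, -1))
    assert to_unit_events([]) == ()


@given(
    st.integers(1, 4).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 3), min_size=n, max_size=n).map(tuple),
            st.lists(events_for(n), max_size=5).map(tuple),
        )
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_unit_decomposition_preserves_effect_and_cost(pseq):
    p, seq = pseq
    units = to_unit_events(seq)
    assert all(abs(ev.b) == 1 for ev in units)
    assert sequence_cost(units) == sequence_cost(seq)
    assert apply_sequence(p, units) == apply_sequence(p, seq)


@given(
    st.integers(1, 3).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 3), min_size=n, max_size=n).map(tuple),
            st.lists(events_for(n), max_size=6).map(tuple),
        )
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_zero_absorption(pseq):
    """A position that hits zero stays zero under any further events."""
    p, seq = pseq
    cur = p
    lost = {i for i, v in enumerate(cur) if v == 0}
    for ev in seq:
        cur = apply_event(cur, ev)
        assert all(cur[i] == 0 for i in lost)
        lost |= {i for i, v in enumerate(cur) if v == 0}


@pytest.mark.parametrize(
    "seq, expected",
    [
        (((1, 1, -1), (2, 2, +1)), True),
        (((2, 2, +1), (1, 1, -1)), False),
        ((), True),
    ],
)
def test_is_sorted(seq, expected):
    assert is_sorted([Event(*e) for e in seq]) is expected


def _two_leaf_tree():
    return CopyNumberTree(
        root=0,
        profiles={0: (2, 2), 1: (3, 2), 2: (2, 0)},
        children={0: (1, 2), 1: (), 2: ()},
        events={(0, 1): (Event(1, 1, 1),), (0, 2): (Event(2, 2, -2),)},
        leaf_labels={1: "s1", 2: "s2"},
    )


def test_tree_cost():
    t = CopyNumberTree(root=0, profiles={0: (2,)})
    assert tree_cost(t) == 0
    assert tree_cost(_two_leaf_tree()) == 3


def test_validate_tree_accepts_consistent_tree():
    assert validate_tree(_two_leaf_tree()) == []


def test_validate_tree_reports_all_violations():
    t = _two_leaf_tree()
    t.profiles[0] = (2, 3)
    t.profiles[1] = (9, 9)
    errs = validate_tree(t)
    assert any("diploid" in e for e in errs)
    assert any("inconsistent" in e for e in errs)


def test_as_profile_rejects_bad_input():
    with pytest.raises(ValueError):
        as_profile([])
    with pytest.raises(ValueError):
        as_profile([2, -1])
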