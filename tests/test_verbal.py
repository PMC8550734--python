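import itertools

import pytest

from spatialcog import oracle
from spatialcog.relations import (
    ParseError,
    Premise,
    Problem,
    encode_relation,
    parse_assertions,
    parse_premise,
)
from spatialcog.verbal import (
    CostModel,
    candidate_queues,
    conclude,
    insert_premise,
    predict,
    preferred_queue,
)


def test_candidate_queues_both_orientations():
    q1, q2 = candidate_queues(parse_premise("left;apple;mango"))
    assert q1.order == ["apple", "mango"] and q1.start == "apple"
    assert q1.raw_links == [(1, 0)]
    assert q2.order == ["mango", "apple"] and q2.start == "mango"
    assert q2.raw_links == [(-1, 0)]


def test_candidate_queues_cardinal_encodings():
    q1, q2 = candidate_queues(parse_premise("north;A;B"))
    assert q1.raw_links == [(0, -1)] and q2.raw_links == [(0, 1)]


def test_candidate_queue_rejects_identical_terms():
    with pytest.raises(ParseError):
        parse_premise("left;apple;apple")


def test_insertion_costs_depend_on_orientation(apple_premises):
    costs = CostModel()
    q1, q2 = candidate_queues(apple_premises[0], costs)
    i1 = insert_premise(q1, apple_premises[1], costs)
    i2 = insert_premise(q2, apple_premises[1], costs)
    assert i1.order == ["apple", "mango", "pear"]
    assert i1.cost == q1.cost + costs.cost_create  # plain append
    assert i2.order == ["mango", "pear", "apple"]
    assert i2.cost == q2.cost + costs.cost_create + costs.cost_break  # severed link


def test_insert_requires_seeded_queue():
    from spatialcog.verbal import VerbalQueue

    empty = VerbalQueue(order=[], raw_links=[], positions={}, start="")
    with pytest.raises(ValueError):
        insert_premise(empty, parse_premise("left;a;b"))


def test_preferred_queue_worked_example(apple_premises):
    q = preferred_queue(apple_premises)
    assert q.order == ["apple", "mango", "pear"] and q.start == "apple"
    rel, determinate = conclude(q, "mango", "pear", "1D")
    assert determinate and rel.name == "left"
    rel, determinate = conclude(q, "pear", "mango", "1D")
    assert determinate and rel.name == "right"


def test_preferred_queue_determinate_chain():
    q = preferred_queue(parse_assertions("left;A;B/left;B;C"))
    assert q.order == ["A", "B", "C"]


def test_preferred_queue_is_global_cost_minimum():
    """Exhaustive check: no candidate construction path is cheaper."""
    costs = CostModel()
    for rels in itertools.product(("left", "right"), repeat=3):
        premises = parse_assertions(
            f"{rels[0]};A;B/{rels[1]};A;C/{rels[2]};C;D"
        )
        preferred = preferred_queue(premises, costs)
        for seed_queue in candidate_queues(premises[0], costs):
            q = seed_queue
            for p in premises[1:]:
                q = insert_premise(q, p, costs)
            assert preferred.cost <= q.cost


def test_preferred_queue_order_is_an_oracle_model():
    for rels in itertools.product(("left", "right"), repeat=2):
        premises = parse_assertions(f"{rels[0]};A;B/{rels[1]};A;C")
        q = preferred_queue(premises)
        orders = {m.axis_order() for m in oracle.enumerate_models(premises)}
        g = q.raw_links[0]
        spatial = tuple(q.order) if g[0] > 0 else tuple(reversed(q.order))
        assert spatial in orders


def test_cardinal_insertion_angle_rule():
    # queue A -> B with B south of A; C south of B is aligned: append
    base = parse_premise("north;A;B")  # A north of B, i.e. B below A
    q1, _ = candidate_queues(base)
    aligned = insert_premise(q1, parse_premise("north;B;C"))
    assert aligned.order == ["A", "B", "C"]
    # C north of B opposes the queue direction: insert before the reference
    opposed = insert_premise(q1, parse_premise("south;B;C"))
    assert opposed.order == ["A", "C", "B"]


def test_cardinal_orthogonal_dot_appends_with_same_conclusion():
    q1, _ = candidate_queues(parse_premise("north;A;B"))
    orthogonal = insert_premise(q1, parse_premise("west;B;C"))
    assert orthogonal.order == ["A", "B", "C"]  # dot = 0 appends
    rel, determinate = conclude(orthogonal, "C", "A", "cardinal")
    assert determinate and rel.name == "south-east"


def test_conclude_sums_encodings(city_premises_determinate):
    q = preferred_queue(parse_assertions("north;A;B/north;B;C"))
    rel, determinate = conclude(q, "C", "A", "cardinal")
    assert determinate and rel.name == "south"
    q2 = preferred_queue(city_premises_determinate)
    rel, determinate = conclude(q2, "frankfurt", "stockholm", "cardinal")
    assert determinate and rel.name == "south-east"


def test_conclude_is_converse_symmetric_when_determinate():
    q = preferred_queue(parse_assertions("south-east;A;B/east;B;C"))
    r_ab, d1 = conclude(q, "A", "C", "cardinal")
    r_ba, d2 = conclude(q, "C", "A", "cardinal")
    assert d1 and d2
    assert r_ab.vec == (-r_ba.vec[0], -r_ba.vec[1])


def test_opposite_relations_trigger_fallback(city_premises_indeterminate):
    q = preferred_queue(city_premises_indeterminate)
    rel, determinate = conclude(q, "paris", "frankfurt", "cardinal")
    assert not determinate  # the summed vector is zero
    assert rel is not None  # forced choice from the incident link
    rel_none, _ = conclude(q, "paris", "frankfurt", "cardinal", fallback="none")
    assert rel_none is None


def test_determinate_cardinal_agrees_with_composition():
    cardinals = [encode_relation(n) for n in
                 ("north", "north-east", "east", "south-east",
                  "south", "south-west", "west", "north-west")]
    for r1, r2 in itertools.product(cardinals, repeat=2):
        premises = (Premise(r1, "A", "B"), Premise(r2, "B", "C"))
        composed = oracle.compose(r1, r2)
        if len(composed) != 1:
            continue
        q = preferred_queue(premises)
        rel, determinate = conclude(q, "A", "C", "cardinal")
        assert determinate and {rel} == set(composed)


def test_predict_verification_and_single_choice(apple_premises):
    accept = Problem(
        premises=apple_premises,
        task_type="verification",
        conclusion=(parse_premise("left;mango;pear"),),
    )
    reject = Problem(
        premises=apple_premises,
        task_type="verification",
        conclusion=(parse_premise("left;pear;mango"),),
    )
    assert predict(accept) is True and predict(reject) is False
    premises = parse_assertions("south-east;A;B/south-east;B;C")
    choices = tuple(
        Premise(encode_relation(n), "C", "A")
        for n in ("north", "north-west", "south-east")
    )
    problem = Problem(premises=premises, task_type="single_choice", choices=choices)
    assert predict(problem).relation.name == "north-west"
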