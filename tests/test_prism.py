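import itertools

import pytest

from spatialcog import oracle
from spatialcog.io import Trial
from spatialcog.prism import (
    PrismParams,
    construct_preferred,
    construct_with_sequence,
    fit,
    mix_arrangements,
    predict,
    vary,
)
from spatialcog.relations import Premise, Problem, encode_relation, parse_assertions, parse_premise


def _order(model):
    return tuple(t.capitalize() for t in model.axis_order())


def test_single_premise_construction():
    model, ledger = construct_preferred(parse_assertions("left;pliers;saw"))
    assert model.position("pliers") == (0, 0) and model.position("saw") == (1, 0)
    assert ledger.total > 0


def test_worked_arrangements_ff_fff_mix(fruit_premises):
    ff, _ = construct_preferred(fruit_premises, "ff")
    fff, _ = construct_preferred(fruit_premises, "fff")
    assert _order(ff) == ("Fig", "Cherry", "Kiwi", "Pear", "Apricot")
    assert _order(fff) == ("Cherry", "Kiwi", "Fig", "Pear", "Apricot")
    mixes = mix_arrangements(fruit_premises)
    assert [_order(m) for m in mixes] == [("Cherry", "Fig", "Kiwi", "Pear", "Apricot")]
    explicit, _ = construct_with_sequence(fruit_premises, ("fff", "fff", "ff", "fff"))
    assert _order(explicit) == ("Cherry", "Fig", "Kiwi", "Pear", "Apricot")


def test_first_fit_costs_more_than_first_free_fit(fruit_premises):
    """Relocations make the ff construction dearer than the fff one."""
    _, ff_cost = construct_preferred(fruit_premises, "ff")
    _, fff_cost = construct_preferred(fruit_premises, "fff")
    assert ff_cost.total > fff_cost.total
    assert ff_cost.relocations > 0 and fff_cost.relocations == 0


def test_cost_is_invariant_under_term_renaming(fruit_premises):
    renamed = tuple(
        Premise(p.relation, p.subject.upper(), p.obj.upper()) for p in fruit_premises
    )
    for strategy in ("ff", "fff"):
        _, a = construct_preferred(fruit_premises, strategy)
        _, b = construct_preferred(renamed, strategy)
        assert a.total == b.total


def test_collision_continues_scan_on_opposite_relations(city_premises_indeterminate):
    """The focus passes the occupied cell, committing to one concrete relation."""
    model, _ = construct_preferred(city_premises_indeterminate, "fff")
    rel = model.relation_between("paris", "frankfurt", "cardinal")
    assert rel is not None  # a single preferred relation despite indeterminacy
    assert rel.name == "south-west"


def test_ff_and_fff_coincide_without_collisions():
    premises = parse_assertions("left;A;B/left;B;C/right;D;C")
    ff, _ = construct_preferred(premises, "ff")
    fff, _ = construct_preferred(premises, "fff")
    assert ff.rank_pattern() == fff.rank_pattern()


def test_preferred_model_is_always_an_oracle_model(fruit_premises, city_premises_indeterminate):
    for premises in (fruit_premises, city_premises_indeterminate):
        for strategy in ("ff", "fff", "mix"):
            model, _ = construct_preferred(premises, strategy)
            assert model.rank_pattern() in {
                m.rank_pattern() for m in oracle.enumerate_models(premises)
            }


def test_vary_enumerates_alternatives_by_revision_distance():
    fork = parse_assertions("left;A;B/left;A;C")
    preferred, _ = construct_preferred(fork, "fff")
    assert vary(preferred, fork, 0) == ()
    alts = vary(preferred, fork, 1)
    assert len(alts) == 1
    assert alts[0].rank_pattern() != preferred.rank_pattern()
    chain = parse_assertions("left;A;B/left;B;C")
    preferred, _ = construct_preferred(chain, "fff")
    assert vary(preferred, chain, 5) == ()  # determinate problem


def test_single_choice_reads_preferred_model(city_premises_determinate):
    choices = tuple(
        Premise(encode_relation(n), "stockholm", "frankfurt")
        for n in ("north-west", "south-east", "north")
    )
    problem = Problem(
        premises=city_premises_determinate, task_type="single_choice", choices=choices
    )
    answer = predict(problem, PrismParams("fff", 0))
    assert answer.relation.name == "north-west"


def _arrangement_problem(premises, order):
    left = encode_relation("left")
    conclusion = tuple(Premise(left, a, b) for a, b in zip(order, order[1:]))
    return Problem(premises=premises, task_type="verification", conclusion=conclusion)


def test_arrangement_verification_depth_zero_vs_deep(fruit_premises):
    fff_order = ("cherry", "kiwi", "fig", "pear", "apricot")
    ff_order = ("fig", "cherry", "kiwi", "pear", "apricot")
    p_fff = _arrangement_problem(fruit_premises, fff_order)
    p_ff = _arrangement_problem(fruit_premises, ff_order)
    assert predict(p_fff, PrismParams("fff", 0)) is True
    assert predict(p_ff, PrismParams("fff", 0)) is False
    assert predict(p_fff, PrismParams("fff", 2)) is True
    assert predict(p_ff, PrismParams("fff", 2)) is True


def test_mix_accepts_any_ff_fff_constructible_arrangement(fruit_premises):
    mix_order = ("cherry", "fig", "kiwi", "pear", "apricot")
    problem = _arrangement_problem(fruit_premises, mix_order)
    assert predict(problem, PrismParams("mix", 0)) is True
    assert predict(problem, PrismParams("fff", 0)) is False
    foil = _arrangement_problem(
        fruit_premises, ("pear", "fig", "cherry", "kiwi", "apricot")
    )
    assert predict(foil, PrismParams("mix", 3)) is False


def test_determinate_single_choice_matches_oracle():
    for r1, r2 in itertools.product(("north", "east", "south-east"), repeat=2):
        premises = parse_assertions(f"{r1};A;B/{r2};B;C")
        possible = oracle.possible_relations(premises, "C", "A")
        if len(possible) != 1:
            continue
        choices = tuple(
            Premise(encode_relation(n), "C", "A")
            for n in ("north", "north-east", "east", "south-east", "south", "south-west", "west", "north-west")
        )
        problem = Problem(premises=premises, task_type="single_choice", choices=choices)
        answer = predict(problem, PrismParams("fff", 0))
        assert answer.relation in possible


def _trials_from(params, premises_list):
    trials = []
    for i, (premises, order) in enumerate(premises_list):
        problem = _arrangement_problem(premises, order)
        trials.append(
            Trial("sim", i + 1, problem, response=predict(problem, params))
        )
    return trials


def test_fit_recovers_generating_params(fruit_premises):
    models = oracle.enumerate_models(fruit_premises)
    arrangements = [m.axis_order() for m in models] + [
        ("pear", "fig", "cherry", "kiwi", "apricot")
    ]
    items = [(fruit_premises, order) for order in arrangements] * 5
    params = PrismParams("ff", 0)
    trials = _trials_from(params, items)
    assert fit(trials) == params


def test_fit_defaults_and_depth_preference(fruit_premises):
    assert fit([]) == PrismParams("fff", 0)
    # a responder accepting every consistent arrangement needs depth
    models = oracle.enumerate_models(fruit_premises)
    trials = []
    for i, m in enumerate(models):
        problem = _arrangement_problem(fruit_premises, m.axis_order())
        trials.append(Trial("sim", i + 1, problem, response=True))
    fitted = fit(trials)
    assert fitted.variation_depth >= 2 or fitted.strategy == "mix"
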