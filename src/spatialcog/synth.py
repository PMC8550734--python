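"""Synthetic benchmark generators for the four experimental designs.

Each generator emulates one design of the benchmark the cognitive models are
evaluated on, with the design's task structure, per-participant trial counts
and consistency ratios:

* ``figural`` — 16 three-term verification problems over the four figures
  (I: A left B / B left C, II: A left B / C right B, III: B right A / B left C,
  IV: B right A / C right B), 8 consistent / 8 inconsistent, fruit terms,
* ``continuity`` — 48 four-term verification problems in continuous
  (A-B, B-C, C-D), semi-continuous (B-C, C-D, A-B) and discontinuous
  (C-D, A-B, B-C) premise orders; 24 consistent / 24 inconsistent, about a
  quarter being easy-to-falsify filter items whose conclusion mirrors a
  premise's relation,
* ``cardinal`` — 64 single-choice problems, one per ordered pair of the eight
  cardinal relations, querying C versus A with all eight options, building
  terms,
* ``smalllarge`` — four structurally distinct 4-premise problems, each paired
  with 6 candidate arrangements (the ff / fff / mix constructions plus three
  inconsistent foils), each combination presented at both the small (fruit)
  and large (tree) scale: 4 x 6 x 2 = 48 arrangement-verification trials.

Materials (term words) are fixed per design seed and shared by all
participants; presentation order is shuffled per participant.  Consistency
labels always derive from the relational oracle, never from construction
shortcuts.  ``simulate_responses`` turns generated problems into a dataset by
querying a generating model and corrupting its answers at a configured error
rate, which is what enables parameter-recovery experiments without human data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import oracle, prism
from .baselines import Model, _options
from .io import Dataset, Trial
from .relations import Premise, Problem, VOCAB_CARDINAL, converse, encode_relation

__all__ = [
    "DesignSpec",
    "SimulatedResponder",
    "FRUITS",
    "BUILDINGS",
    "gen_figural",
    "gen_continuity",
    "gen_cardinal",
    "gen_smalllarge",
    "generate",
    "simulate_responses",
]

FRUITS = [
    "apple", "mango", "pear", "apricot", "fig", "kiwi", "cherry", "peach",
    "plum", "grape", "lemon", "lime", "melon", "banana", "orange", "papaya",
    "quince", "date", "olive", "guava",
]

BUILDINGS = [
    "church", "school", "castle", "tower", "station", "museum", "library",
    "theater", "bank", "hotel", "bakery", "hospital", "townhall", "harbor",
    "market", "chapel",
]

DESIGNS = ("figural", "continuity", "cardinal", "smalllarge")


@dataclass(frozen=True)
class DesignSpec:
    """One benchmark design instance: which design, how many people, seed."""

    design: str
    n_participants: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {DESIGNS}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class SimulatedResponder:
    """A generating model plus an error process.

    With probability ``error_rate`` the model's response is replaced by a
    uniform draw over the *other* response options.
    """

    model_factory: Callable[[], Model]
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _materials_rng(spec: DesignSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), 7]))


def _participant_order(
    spec: DesignSpec, n_items: int
) -> List[np.ndarray]:
    orders = []
    for i in range(spec.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), 11, i]))
        orders.append(rng.permutation(n_items))
    return orders


def _deal(rng: np.random.Generator, words: Sequence[str], k: int) -> List[str]:
    idx = rng.choice(len(words), size=k, replace=False)
    return [words[int(i)] for i in idx]


def _as_dataset(
    spec: DesignSpec, items: List[Tuple[Problem, str]]
) -> Dataset:
    """Shuffle item order per participant and wrap into response-less trials."""
    orders = _participant_order(spec, len(items))
    trials: List[Trial] = []
    width = max(2, len(str(spec.n_participants)))
    for i, order in enumerate(orders):
        participant = f"p{i + 1:0{width}d}"
        for seq, j in enumerate(order, start=1):
            problem, condition = items[int(j)]
            trials.append(
                Trial(
                    participant=participant,
                    sequence=seq,
                    problem=problem,
                    response=None,
                    condition=condition,
                )
            )
    return Dataset.from_trials(trials)


# ---------------------------------------------------------------------------
# Design 1: figural effect (three-term verification)
# ---------------------------------------------------------------------------

_FIGURES: Dict[str, Tuple[Tuple[str, int, int], Tuple[str, int, int]]] = {
    # (relation, subject index, object index) over the A-B-C order (0,1,2)
    "I": (("left", 0, 1), ("left", 1, 2)),
    "II": (("left", 0, 1), ("right", 2, 1)),
    "III": (("right", 1, 0), ("left", 1, 2)),
    "IV": (("right", 1, 0), ("right", 2, 1)),
}


def gen_figural(spec: DesignSpec) -> Dataset:
    """16 problems: 4 figures x {consistent, inconsistent} x 2 phrasings."""
    rng = _materials_rng(spec)
    items: List[Tuple[Problem, str]] = []
    for figure, assertions in _FIGURES.items():
        for consistent in (True, False):
            for phrasing in ("left", "right"):
                terms = _deal(rng, FRUITS, 3)
                premises = tuple(
                    Premise(encode_relation(rel), terms[s], terms[o])
                    for rel, s, o in assertions
                )
                a, c = terms[0], terms[2]  # spatial order is a < b < c
                if phrasing == "left":
                    conclusion = Premise(encode_relation("left"), a, c)
                else:
                    conclusion = Premise(encode_relation("right"), c, a)
                if not consistent:
                    conclusion = Premise(
                        converse(conclusion.relation), conclusion.subject, conclusion.obj
                    )
                problem = Problem(
                    premises=premises,
                    task_type="verification",
                    conclusion=(conclusion,),
                )
                items.append((problem, f"figure-{figure}"))
    return _as_dataset(spec, items)


# ---------------------------------------------------------------------------
# Design 2: continuity effect (four-term verification)
# ---------------------------------------------------------------------------

_ORDERS: Dict[str, Tuple[Tuple[int, int], ...]] = {
    # premise term-index pairs over the A-B-C-D order (0..3)
    "continuous": ((0, 1), (1, 2), (2, 3)),
    "semi-continuous": ((1, 2), (2, 3), (0, 1)),
    "discontinuous": ((2, 3), (0, 1), (1, 2)),
}


def gen_continuity(spec: DesignSpec) -> Dataset:
    """48 problems: 3 orders x (8 consistent + 4 inconsistent + 4 filter)."""
    rng = _materials_rng(spec)
    items: List[Tuple[Problem, str]] = []
    for order_name, pairs in _ORDERS.items():
        kinds = ["consistent"] * 8 + ["inconsistent"] * 4 + ["filter"] * 4
        for k, kind in enumerate(kinds):
            terms = _deal(rng, FRUITS, 4)
            premises = []
            for s, o in pairs:
                if rng.random() < 0.5:
                    premises.append(Premise(encode_relation("left"), terms[s], terms[o]))
                else:
                    premises.append(Premise(encode_relation("right"), terms[o], terms[s]))
            premises = tuple(premises)
            a, d = terms[0], terms[3]
            if kind == "filter":
                # conclusion mirrors one premise's relation with the same term
                # order: falsifiable by a single converse check
                p = premises[int(rng.integers(len(premises)))]
                conclusion = Premise(converse(p.relation), p.subject, p.obj)
                condition = f"{order_name}-filter"
            else:
                rel = "left" if rng.random() < 0.5 else "right"
                if rel == "left":
                    conclusion = Premise(encode_relation("left"), a, d)
                else:
                    conclusion = Premise(encode_relation("right"), d, a)
                if kind == "inconsistent":
                    conclusion = Premise(
                        converse(conclusion.relation), conclusion.subject, conclusion.obj
                    )
                condition = order_name
            problem = Problem(
                premises=premises,
                task_type="verification",
                conclusion=(conclusion,),
            )
            items.append((problem, condition))
    return _as_dataset(spec, items)


# ---------------------------------------------------------------------------
# Design 3: preference effect (cardinal single choice)
# ---------------------------------------------------------------------------


def gen_cardinal(spec: DesignSpec) -> Dataset:
    """64 problems: the full r1 x r2 cross, querying C versus A, 8 options."""
    rng = _materials_rng(spec)
    items: List[Tuple[Problem, str]] = []
    relations = [encode_relation(name) for name in VOCAB_CARDINAL]
    for r1, r2 in itertools.product(relations, repeat=2):
        a, b, c = _deal(rng, BUILDINGS, 3)
        premises = (Premise(r1, a, b), Premise(r2, b, c))
        choices = tuple(Premise(r, c, a) for r in relations)
        problem = Problem(
            premises=premises, task_type="single_choice", choices=choices
        )
        n_possible = len(oracle.possible_relations(premises, c, a))
        condition = "determinate" if n_possible == 1 else "indeterminate"
        items.append((problem, condition))
    return _as_dataset(spec, items)


# ---------------------------------------------------------------------------
# Design 4: small-large-scale relations (arrangement verification)
# ---------------------------------------------------------------------------

# four structurally distinct premise schemata over term slots t0..t4;
# each has two colliding insertions so ff / fff / mix arrangements differ
_SMALLLARGE_STRUCTURES: Tuple[Tuple[Tuple[str, int, int], ...], ...] = (
    (("left", 1, 0), ("left", 2, 1), ("left", 3, 1), ("left", 4, 3)),
    (("right", 1, 0), ("right", 2, 1), ("right", 3, 1), ("right", 4, 3)),
    (("left", 1, 0), ("left", 2, 1), ("left", 3, 1), ("left", 4, 1)),
    (("right", 1, 0), ("right", 2, 1), ("right", 3, 1), ("right", 4, 1)),
)


def _arrangement_assertions(order: Sequence[str]) -> Tuple[Premise, ...]:
    """Encode a left-to-right term order as four adjacent 'left' assertions."""
    left = encode_relation("left")
    return tuple(Premise(left, a, b) for a, b in zip(order, order[1:]))


def _foil_orders(
    premises: Tuple[Premise, ...], terms: Sequence[str], count: int
) -> List[Tuple[str, ...]]:
    model_orders = {m.axis_order() for m in oracle.enumerate_models(premises)}
    foils: List[Tuple[str, ...]] = []
    for perm in itertools.permutations(sorted(terms)):
        if perm not in model_orders:
            foils.append(perm)
        if len(foils) == count:
            return foils
    raise RuntimeError("not enough inconsistent arrangements")  # pragma: no cover


def gen_smalllarge(spec: DesignSpec) -> Dataset:
    """48 trials: 4 structures x 6 arrangements x {small, large} scale."""
    rng = _materials_rng(spec)
    items: List[Tuple[Problem, str]] = []
    for s_idx, schema in enumerate(_SMALLLARGE_STRUCTURES, start=1):
        base_terms = _deal(rng, FRUITS, 5)
        for scale in ("small", "large"):
            terms = (
                base_terms if scale == "small" else [f"{t}-tree" for t in base_terms]
            )
            premises = tuple(
                Premise(encode_relation(rel), terms[s], terms[o])
                for rel, s, o in schema
            )
            ff_model, _ = prism.construct_preferred(premises, "ff")
            fff_model, _ = prism.construct_preferred(premises, "fff")
            mixes = prism.mix_arrangements(premises)
            arrangements: List[Tuple[Tuple[str, ...], str]] = [
                (fff_model.axis_order(), "fff"),
                (mixes[0].axis_order(), "mix"),
                (ff_model.axis_order(), "ff"),
            ]
            for foil in _foil_orders(premises, terms, 3):
                arrangements.append((foil, "foil"))
            for order, kind in arrangements:
                problem = Problem(
                    premises=premises,
                    task_type="verification",
                    conclusion=_arrangement_assertions(order),
                )
                items.append((problem, f"{scale}-{kind}-s{s_idx}"))
    return _as_dataset(spec, items)


_GENERATORS = {
    "figural": gen_figural,
    "continuity": gen_continuity,
    "cardinal": gen_cardinal,
    "smalllarge": gen_smalllarge,
}


def generate(spec: DesignSpec) -> Dataset:
    """Dispatch to the design's generator."""
    return _GENERATORS[spec.design](spec)


# ---------------------------------------------------------------------------
# Simulated responders
# ---------------------------------------------------------------------------


def simulate_responses(problems: Dataset, responder: SimulatedResponder) -> Dataset:
    """Fill in responses from a generating model, corrupted at ``error_rate``.

    One model instance and one random stream per participant; byte-identical
    output for identical seeds.
    """
    out: List[Trial] = []
    for p_idx, participant in enumerate(problems.participants):
        model = responder.model_factory()
        rng = np.random.default_rng(
            np.random.SeedSequence([responder.seed % (2**31), 13, p_idx])
        )
        for trial in problems.for_participant(participant):
            response = model.predict(trial.problem, rng)
            if responder.error_rate and rng.random() < responder.error_rate:
                others = [o for o in _options(trial.problem) if o != response]
                response = others[int(rng.integers(len(others)))]
            out.append(
                Trial(
                    participant=trial.participant,
                    sequence=trial.sequence,
                    problem=trial.problem,
                    response=response,
                    condition=trial.condition,
                )
            )
    return Dataset.from_trials(out)
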