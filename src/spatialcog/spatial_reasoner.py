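"""Mental-model-theory reasoner: incremental coordinate models and variants.

Premises are integrated one by one into a 3-D coordinate model (z fixed at 0
for the 1-D/2-D tasks handled here).  The first term of the first premise sits
at the origin; every later term is written to the first free lattice cell
scanning outward from its reference term in the premise direction.  Checking a
putative assertion against the growing model yields one of four outcomes:

* ``truth`` — it follows validly from the premises,
* ``falsity`` — it is inconsistent with the premises,
* ``weak_falsification`` — it holds in the initially constructed model but an
  alternative model refutes it,
* ``weak_truthification`` — it fails in the initial model, but reinterpreting
  the premises yields a model consistent with all of them plus the assertion.

Four predictive variants interpret the outcomes: *skeptical* accepts only
``truth``; *initial* accepts what the initial model shows (``truth`` or
``weak_falsification``); *credulous* accepts everything except ``falsity``;
*adapted* picks the sub-variant that best fits a participant's responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Optional, Sequence, Tuple

from . import oracle
from .relations import Premise, Problem

__all__ = [
    "CoordinateModel",
    "TRUTH",
    "FALSITY",
    "WEAK_FALSIFICATION",
    "WEAK_TRUTHIFICATION",
    "ACCEPTED_OUTCOMES",
    "VARIANTS",
    "build_model",
    "integrate",
    "predict",
    "fit_adapted",
]

Coord = Tuple[int, int, int]

TRUTH = "truth"
FALSITY = "falsity"
WEAK_FALSIFICATION = "weak_falsification"
WEAK_TRUTHIFICATION = "weak_truthification"

#: outcome sets each predictive variant accepts as "true"
ACCEPTED_OUTCOMES: Dict[str, frozenset] = {
    "skeptical": frozenset({TRUTH}),
    "initial": frozenset({TRUTH, WEAK_FALSIFICATION}),
    "credulous": frozenset({TRUTH, WEAK_FALSIFICATION, WEAK_TRUTHIFICATION}),
}

#: tie-break order for the adapted variant
VARIANTS: Tuple[str, ...] = ("skeptical", "initial", "credulous")


@dataclass
class CoordinateModel:
    """Term -> integer coordinate triple, in insertion order."""

    positions: Dict[str, Coord] = field(default_factory=dict)
    order: Tuple[str, ...] = ()
    consistent: bool = True

    def holds(self, premise: Premise) -> bool:
        sx, sy, _ = self.positions[premise.subject]
        ox, oy, _ = self.positions[premise.obj]
        sign = lambda v: (v > 0) - (v < 0)
        return (sign(sx - ox), sign(sy - oy)) == premise.relation.vec

    def axis_order(self, axis: int = 0) -> Tuple[str, ...]:
        other = 1 - axis
        return tuple(
            t
            for t, _ in sorted(
                self.positions.items(), key=lambda tc: (tc[1][axis], tc[1][other])
            )
        )


def _scan_free(
    occupied: Dict[Coord, str], start: Coord, direction: Tuple[int, int]
) -> Coord:
    """First free cell from ``start`` moving stepwise along ``direction``."""
    x, y, z = start
    dx, dy = direction
    while True:
        x, y = x + dx, y + dy
        if (x, y, z) not in occupied:
            return (x, y, z)


@lru_cache(maxsize=16384)
def _build_cached(premises: Tuple[Premise, ...]) -> CoordinateModel:
    model = CoordinateModel()
    occupied: Dict[Coord, str] = {}
    order: list[str] = []

    def place(term: str, coord: Coord) -> None:
        model.positions[term] = coord
        occupied[coord] = term
        order.append(term)

    pending = list(premises)
    progress = True
    while pending and progress:
        progress = False
        for premise in list(pending):
            s_in = premise.subject in model.positions
            o_in = premise.obj in model.positions
            if not model.positions:
                # first premise: subject at the origin, object adjacent
                place(premise.subject, (0, 0, 0))
                vx, vy = premise.relation.vec
                place(premise.obj, (-vx, -vy, 0))
            elif s_in and o_in:
                if not model.holds(premise) and not oracle.satisfiable(premises):
                    model.consistent = False
            elif s_in:
                # object lies opposite the premise direction from the subject
                vx, vy = premise.relation.vec
                coord = _scan_free(occupied, model.positions[premise.subject], (-vx, -vy))
                place(premise.obj, coord)
            elif o_in:
                coord = _scan_free(
                    occupied, model.positions[premise.obj], premise.relation.vec
                )
                place(premise.subject, coord)
            else:
                continue  # both terms unattached: hold until linkable
            pending.remove(premise)
            progress = True
    if pending:
        raise ValueError("premises are not connectable into one model")
    model.order = tuple(order)
    return model


def build_model(premises: Sequence[Premise]) -> CoordinateModel:
    """Deterministic initial model with first-free-cell scanning.

    Unattached premises (neither term placed yet) are buffered and integrated
    once one of their terms appears.  A premise over two already-placed terms
    that fails in the model flags it inconsistent only when no alternative
    model of all premises exists.
    """
    return _build_cached(tuple(premises))


def integrate(premises_so_far: Sequence[Premise], putative: Premise) -> str:
    """Classify a putative assertion against the premises so far."""
    known: set[str] = set()
    for p in premises_so_far:
        known.update(p.terms())
    for t in putative.terms():
        if t not in known:
            raise KeyError(f"putative term not in premises: {t!r}")
    status = oracle.verify(premises_so_far, putative)
    if status == "valid":
        return TRUTH
    if status == "contradicted":
        return FALSITY
    initial = build_model(premises_so_far)
    return WEAK_FALSIFICATION if initial.holds(putative) else WEAK_TRUTHIFICATION


def _accepts(outcome: str, variant: str) -> bool:
    return outcome in ACCEPTED_OUTCOMES[variant]


def predict(problem: Problem, variant: str):
    """Prediction of one variant for a problem.

    Verification with a single conclusion: True iff its integration outcome is
    accepted.  Arrangement verification (multi-assertion conclusion): the
    assertions are integrated sequentially as putative premises and all
    outcomes must be accepted.  Single choice: prefer a choice with outcome
    ``truth``, else the first policy-accepted choice, else the first choice.
    """
    if variant not in ACCEPTED_OUTCOMES:
        raise ValueError(f"unknown variant: {variant!r}")
    if problem.task_type == "verification":
        assert problem.conclusion is not None
        premises = list(problem.premises)
        for putative in problem.conclusion:
            outcome = integrate(premises, putative)
            if not _accepts(outcome, variant):
                return False
            premises.append(putative)
        return True
    assert problem.choices is not None
    outcomes = [integrate(problem.premises, c) for c in problem.choices]
    for c, outcome in zip(problem.choices, outcomes):
        if outcome == TRUTH:
            return c
    for c, outcome in zip(problem.choices, outcomes):
        if _accepts(outcome, variant):
            return c
    return problem.choices[0]


def fit_adapted(person_trials: Sequence) -> str:
    """Sub-variant with the highest accuracy on a participant's trials.

    ``person_trials`` is a sequence of objects with ``problem`` and
    ``response`` attributes.  Ties break skeptical > initial > credulous;
    empty input defaults to skeptical.
    """
    if not person_trials:
        return "skeptical"
    best, best_score = "skeptical", -1.0
    for variant in VARIANTS:
        score = sum(
            1 for t in person_trials if predict(t.problem, variant) == t.response
        )
        if score > best_score:
            best, best_score = variant, score
    return best
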