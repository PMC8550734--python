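"""PRISM: preferred-model construction on a spatial array with a focus.

A spatial focus writes terms into a discrete 2-D array, one term per cell.
Difficulty is the number of focus operations spent.  Two insertion strategies
realize the preference effect:

* ``ff`` (first fit) — the new term is written to the cell adjacent to its
  reference term in the required direction; any occupants from that cell
  outward are shifted one cell further,
* ``fff`` (first free fit) — the focus scans from the reference term in the
  required direction to the first genuinely free cell and writes there,
* ``mix`` — an arrangement class: anything constructible by some per-premise
  ff/fff choice sequence (construction for production uses ``fff``).

When the required direction collides with an occupied cell the focus simply
continues in that direction; on logically indeterminate problems with opposite
relations this is what commits PRISM to one concrete preferred relation.
The preferred model can be *varied* by minimal changes to visit alternative
models in order of revision distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import oracle
from .oracle import MentalModel
from .relations import Premise, Problem, Relation, relation_from_vec

__all__ = [
    "CostLedger",
    "PrismParams",
    "SpatialArray",
    "COST_WEIGHTS",
    "construct_preferred",
    "vary",
    "predict",
    "fit",
]

Cell = Tuple[int, int]

#: operation weights: one focus step, one write, one term relocation
COST_WEIGHTS: Dict[str, int] = {"move": 1, "write": 1, "relocate": 2}

STRATEGIES: Tuple[str, ...] = ("ff", "fff", "mix")


@dataclass
class CostLedger:
    """Counts of focus operations during construction."""

    moves: int = 0
    writes: int = 0
    relocations: int = 0

    @property
    def total(self) -> int:
        return (
            COST_WEIGHTS["move"] * self.moves
            + COST_WEIGHTS["write"] * self.writes
            + COST_WEIGHTS["relocate"] * self.relocations
        )


@dataclass(frozen=True)
class PrismParams:
    """Insertion strategy plus how many alternative models are considered."""

    strategy: str = "fff"
    variation_depth: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.variation_depth < 0:
            raise ValueError("variation_depth must be >= 0")


@dataclass
class SpatialArray:
    """Unbounded 2-D grid, one term per cell, with a focus position."""

    cells: Dict[Cell, str] = field(default_factory=dict)
    positions: Dict[str, Cell] = field(default_factory=dict)
    focus: Cell = (0, 0)
    consistent: bool = True

    def write(self, term: str, cell: Cell, ledger: CostLedger) -> None:
        if cell in self.cells:
            raise ValueError(f"cell {cell} already occupied by {self.cells[cell]!r}")
        self.cells[cell] = term
        self.positions[term] = cell
        self.focus = cell
        ledger.writes += 1

    def insert(self, premise: Premise, strategy: str, ledger: CostLedger) -> None:
        """Integrate one premise under ``ff`` or ``fff``."""
        if strategy not in ("ff", "fff"):
            raise ValueError(f"insert expects 'ff' or 'fff', got {strategy!r}")
        s_in = premise.subject in self.positions
        o_in = premise.obj in self.positions
        vx, vy = premise.relation.vec
        if not self.positions:
            self.write(premise.subject, self.focus, ledger)
            ledger.moves += 1
            self.write(
                premise.obj, (self.focus[0] - vx, self.focus[1] - vy), ledger
            )
            return
        if s_in and o_in:
            if not self._holds(premise) and not oracle.satisfiable(
                tuple(self._as_premise_check())
            ):
                self.consistent = False
            return
        if s_in:
            new, ref, direction = premise.obj, premise.subject, (-vx, -vy)
        elif o_in:
            new, ref, direction = premise.subject, premise.obj, (vx, vy)
        else:
            raise KeyError("no premise term in array")  # caller buffers these
        self._insert_from(new, self.positions[ref], direction, strategy, ledger)

    def _insert_from(
        self, term: str, ref: Cell, direction: Tuple[int, int], strategy: str, ledger: CostLedger
    ) -> None:
        dx, dy = direction
        target = (ref[0] + dx, ref[1] + dy)
        ledger.moves += 1
        if strategy == "fff":
            while target in self.cells:
                target = (target[0] + dx, target[1] + dy)
                ledger.moves += 1
            self.write(term, target, ledger)
            return
        # ff: claim the adjacent cell, shifting the occupied chain outward
        chain: List[str] = []
        probe = target
        while probe in self.cells:
            chain.append(self.cells[probe])
            probe = (probe[0] + dx, probe[1] + dy)
        for occupant in reversed(chain):
            old = self.positions[occupant]
            new_cell = (old[0] + dx, old[1] + dy)
            del self.cells[old]
            self.cells[new_cell] = occupant
            self.positions[occupant] = new_cell
            ledger.relocations += 1
        self.write(term, target, ledger)

    def _holds(self, premise: Premise) -> bool:
        sx, sy = self.positions[premise.subject]
        ox, oy = self.positions[premise.obj]
        sign = lambda v: (v > 0) - (v < 0)
        return (sign(sx - ox), sign(sy - oy)) == premise.relation.vec

    def _as_premise_check(self):
        return getattr(self, "_premises_seen", ())

    def to_mental_model(self) -> MentalModel:
        terms = tuple(self.positions)
        coords = tuple(self.positions[t] for t in terms)
        return MentalModel(terms=terms, coords=coords)


def _construct(
    premises: Tuple[Premise, ...], strategy_seq: Tuple[str, ...]
) -> Tuple[SpatialArray, CostLedger]:
    array = SpatialArray()
    ledger = CostLedger()
    pending = list(zip(premises, strategy_seq))
    seen: List[Premise] = []
    progress = True
    while pending and progress:
        progress = False
        for premise, strat in list(pending):
            linked = (
                not array.positions
                or premise.subject in array.positions
                or premise.obj in array.positions
            )
            if not linked:
                continue
            array._premises_seen = tuple(seen) + (premise,)
            array.insert(premise, strat, ledger)
            seen.append(premise)
            pending.remove((premise, strat))
            progress = True
    if pending:
        raise ValueError("premises are not connectable into one model")
    return array, ledger


@lru_cache(maxsize=16384)
def _construct_cached(
    premises: Tuple[Premise, ...], strategy_seq: Tuple[str, ...]
) -> Tuple[MentalModel, int, bool]:
    array, ledger = _construct(premises, strategy_seq)
    return array.to_mental_model(), ledger.total, array.consistent


def construct_preferred(
    premises: Sequence[Premise], strategy: str = "fff"
) -> Tuple[MentalModel, CostLedger]:
    """Deterministic preferred model and its operation costs.

    ``mix`` constructs with ``fff`` (the mix class matters only for
    arrangement acceptance, see :func:`predict`).
    """
    premises = tuple(premises)
    per_premise = "fff" if strategy == "mix" else strategy
    array, ledger = _construct(premises, (per_premise,) * len(premises))
    construct_preferred.last_consistent = array.consistent  # type: ignore[attr-defined]
    return array.to_mental_model(), ledger


def construct_with_sequence(
    premises: Sequence[Premise], strategy_seq: Sequence[str]
) -> Tuple[MentalModel, CostLedger]:
    """Construct a model with an explicit per-premise ff/fff choice sequence."""
    array, ledger = _construct(tuple(premises), tuple(strategy_seq))
    return array.to_mental_model(), ledger


def mix_arrangements(premises: Sequence[Premise]) -> Tuple[MentalModel, ...]:
    """Models constructible by a mixed ff/fff sequence but by neither pure one.

    Returned in deterministic enumeration order of the choice sequences.
    """
    premises = tuple(premises)
    pure = {
        _construct_cached(premises, ("ff",) * len(premises))[0].rank_pattern(),
        _construct_cached(premises, ("fff",) * len(premises))[0].rank_pattern(),
    }
    out: List[MentalModel] = []
    seen = set(pure)
    for seq in itertools.product(("ff", "fff"), repeat=len(premises)):
        model, _, _ = _construct_cached(premises, seq)
        key = model.rank_pattern()
        if key not in seen:
            seen.add(key)
            out.append(model)
    return tuple(out)


def _mix_class(premises: Tuple[Premise, ...]) -> Tuple[Tuple[Tuple[int, ...], ...], ...]:
    """Rank patterns of every model constructible by some ff/fff sequence."""
    patterns = set()
    for seq in itertools.product(("ff", "fff"), repeat=len(premises)):
        model, _, _ = _construct_cached(premises, seq)
        patterns.add(model.rank_pattern())
    return tuple(sorted(patterns))


def _revision_distance(a: MentalModel, b: MentalModel) -> int:
    """Number of terms whose per-axis rank order changed between two models."""
    pa, pb = a.rank_pattern(), b.rank_pattern()
    index = {t: i for i, t in enumerate(a.terms)}
    moved = 0
    for t in a.terms:
        i, j = index[t], b.terms.index(t)
        if (pa[0][i], pa[1][i]) != (pb[0][j], pb[1][j]):
            moved += 1
    return moved


def vary(
    model: MentalModel, premises: Sequence[Premise], depth: int
) -> Tuple[MentalModel, ...]:
    """Up to ``depth`` alternative models ordered by revision distance."""
    if depth <= 0:
        return ()
    preferred_key = model.rank_pattern()
    alternatives = [
        m for m in oracle.enumerate_models(premises) if m.rank_pattern() != preferred_key
    ]
    alternatives.sort(key=lambda m: (_revision_distance(model, m), m.rank_pattern()))
    return tuple(alternatives[:depth])


def _holds_in(model: MentalModel, premise: Premise) -> bool:
    return model.holds(premise)


def _arrangement_pattern(conclusion: Sequence[Premise], terms: Sequence[str]):
    """Canonical rank pattern implied by an arrangement's assertions."""
    models = oracle.enumerate_models(tuple(conclusion))
    if len(models) != 1:
        return None  # arrangement does not pin down a unique qualitative order
    m = models[0]
    index = {t: i for i, t in enumerate(m.terms)}
    pat = m.rank_pattern()
    try:
        return tuple(
            tuple(pat[axis][index[t]] for t in terms) for axis in (0, 1)
        )
    except KeyError:
        return None


def _model_pattern_over(model: MentalModel, terms: Sequence[str]):
    index = {t: i for i, t in enumerate(model.terms)}
    pat = model.rank_pattern()
    return tuple(tuple(pat[axis][index[t]] for t in terms) for axis in (0, 1))


def predict(problem: Problem, params: PrismParams):
    """PRISM's response to a problem.

    Verification with one conclusion: True iff it holds in the preferred
    model, or failing that, in some alternative within ``variation_depth``
    (a preferred-model True is never overturned).  Single choice: read the
    queried relation straight off the preferred model.  Arrangement
    verification: True iff the arrangement equals the preferred model's
    qualitative order (for ``mix``: any ff/fff-constructible order) or any
    model within ``variation_depth``.
    """
    premises = tuple(problem.premises)
    preferred, _ = construct_preferred(premises, params.strategy)
    if problem.task_type == "single_choice":
        assert problem.choices is not None
        subject, obj = problem.choices[0].subject, problem.choices[0].obj
        rel = preferred.relation_between(subject, obj, problem.vocabulary)
        if rel is None:
            raise ValueError("queried pair decodes to (0,0); cells must be distinct")
        for c in problem.choices:
            if c.relation == rel and (c.subject, c.obj) == (subject, obj):
                return c
        return problem.choices[0]
    assert problem.conclusion is not None
    if len(problem.conclusion) == 1:
        conclusion = problem.conclusion[0]
        if conclusion.subject not in preferred.terms or conclusion.obj not in preferred.terms:
            return False
        if preferred.holds(conclusion):
            return True
        for alt in vary(preferred, premises, params.variation_depth):
            if alt.holds(conclusion):
                return True
        return False
    # arrangement verification
    terms = sorted(problem.term_set())
    target = _arrangement_pattern(problem.conclusion, terms)
    if target is None:
        return False
    accepted = {_model_pattern_over(preferred, terms)}
    if params.strategy == "mix":
        for seq in itertools.product(("ff", "fff"), repeat=len(premises)):
            m, _, _ = _construct_cached(premises, seq)
            accepted.add(_model_pattern_over(m, terms))
    for alt in vary(preferred, premises, params.variation_depth):
        accepted.add(_model_pattern_over(alt, terms))
    return target in accepted


def fit(person_trials: Sequence) -> PrismParams:
    """Grid-search strategy x depth maximizing accuracy on one participant.

    Ties prefer lower depth, then fff > ff > mix.  Empty input returns the
    default ``(fff, 0)``.
    """
    if not person_trials:
        return PrismParams("fff", 0)
    best: Optional[PrismParams] = None
    best_score = -1
    for depth in (0, 1, 2, 3):
        for strategy in ("fff", "ff", "mix"):
            params = PrismParams(strategy, depth)
            score = sum(
                1 for t in person_trials if predict(t.problem, params) == t.response
            )
            if score > best_score:
                best, best_score = params, score
    assert best is not None
    return best
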