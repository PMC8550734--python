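"""Queue-based verbal reasoning model with the cardinal-direction extension.

Reasoners are assumed to hold an ordered *queue* of terms with directed links,
starting at the first-inserted term.  Insertion follows two rules: a new
object placed *behind* an object of the queue (relative to the queue's travel
direction) is appended at the end; one placed *in front of* an object is
inserted directly before it, which requires breaking an existing link.
Each candidate construction path accumulates a cost (creating a link is
cheaper than breaking one) and the cheapest queue is the preferred model.

For cardinal directions every link carries a 2-D direction encoding (+1 for
north/east components, -1 for south/west).  The front/behind test becomes the
sign of the dot product between the new relation's direction and the queue
direction; a negative dot product ("angle > 90 degrees") inserts before the
reference object, otherwise the object is appended.  Conclusions are read off
by summing the encodings between the two queried terms; a zero-vector sum
means the queue carries no net information and a forced-choice fallback
answers from the single link incident to the queried term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from . import oracle
from .relations import Premise, Problem, Relation, relation_from_vec

__all__ = [
    "CostModel",
    "VerbalQueue",
    "candidate_queues",
    "insert_premise",
    "preferred_queue",
    "conclude",
    "predict",
]

Vec = Tuple[int, int]

_sign = lambda v: (v > 0) - (v < 0)


@dataclass(frozen=True)
class CostModel:
    """Link-operation costs; breaking must cost more than creating."""

    cost_create: float = 1.0
    cost_break: float = 2.0
    search_preference: str = "left-to-right"

    def __post_init__(self) -> None:
        if self.cost_break <= self.cost_create:
            raise ValueError("cost_break must exceed cost_create")


@dataclass
class VerbalQueue:
    """Ordered terms with link encodings and qualitative positions.

    ``order`` lists terms in traversal order from the start pointer.
    ``raw_links[i]`` is the premise-derived direction encoding of the link
    from ``order[i]`` to ``order[i+1]``.  ``positions`` accumulate unit steps
    (``pos(new) = pos(ref) + direction``) so that summing information between
    two terms is exact even after link rewiring; on never-rewired queues the
    position difference equals the raw link sum.
    """

    order: List[str]
    raw_links: List[Vec]
    positions: Dict[str, Vec]
    start: str
    vocabulary: str = "1D"
    cost: float = 0.0
    consistent: bool = True

    def copy(self) -> "VerbalQueue":
        return VerbalQueue(
            order=list(self.order),
            raw_links=list(self.raw_links),
            positions=dict(self.positions),
            start=self.start,
            vocabulary=self.vocabulary,
            cost=self.cost,
            consistent=self.consistent,
        )

    def direction_at(self, term: str) -> Vec:
        """Encoding of the link adjacent to ``term`` (toward the interior)."""
        i = self.order.index(term)
        if i < len(self.raw_links):
            return self.raw_links[i]
        return self.raw_links[i - 1]

    def queue_direction(self, ref: str) -> Vec:
        """Queue direction for the angle test: the link adjacent to ``ref``."""
        i = self.order.index(ref)
        if i > 0:
            return self.raw_links[i - 1]
        return self.raw_links[0]

    def summed_vector(self, from_term: str, to_term: str) -> Vec:
        """Net direction information from one term to the other.

        In the 1-D vocabulary the queue order is spatially monotone, so the
        raw link encodings along the queue path are summed directly.  In the
        cardinal vocabulary links may have been rewired by insert-before
        operations, so the rewiring-aware positions are differenced instead;
        this is what lets opposite-relation problems sum to the zero vector.
        """
        if self.vocabulary == "1D":
            i, j = self.order.index(from_term), self.order.index(to_term)
            lo, hi = min(i, j), max(i, j)
            sx = sum(v[0] for v in self.raw_links[lo:hi])
            sy = sum(v[1] for v in self.raw_links[lo:hi])
            return (sx, sy) if i <= j else (-sx, -sy)
        fx, fy = self.positions[from_term]
        tx, ty = self.positions[to_term]
        return (tx - fx, ty - fy)


def candidate_queues(premise: Premise, costs: CostModel = CostModel()) -> Tuple[VerbalQueue, VerbalQueue]:
    """Both orientations of the first premise, start pointer marked.

    For "apple left mango": ``apple* -> mango`` (start apple, link pointing
    right) and ``apple <- mango*`` (start mango, link pointing left).
    """
    vx, vy = premise.relation.vec  # pos(subject) - pos(obj)
    sub, obj = premise.subject, premise.obj
    voc = premise.relation.vocabulary
    q1 = VerbalQueue(
        order=[sub, obj],
        raw_links=[(-vx, -vy)],
        positions={sub: (0, 0), obj: (-vx, -vy)},
        start=sub,
        vocabulary=voc,
        cost=costs.cost_create,
    )
    q2 = VerbalQueue(
        order=[obj, sub],
        raw_links=[(vx, vy)],
        positions={obj: (0, 0), sub: (vx, vy)},
        start=obj,
        vocabulary=voc,
        cost=costs.cost_create,
    )
    return q1, q2


def insert_premise(
    queue: VerbalQueue, premise: Premise, costs: CostModel = CostModel()
) -> VerbalQueue:
    """Insert the premise's new term into a copy of the queue.

    Exactly one premise term must be new.  The placement rule is shared by
    the 1-D and cardinal vocabularies: with ``d`` the direction of the new
    object relative to its reference and ``g`` the queue direction at the
    reference, ``d . g < 0`` inserts directly before the reference (breaking
    a link if one enters it), otherwise the object is appended at the end.
    """
    if not queue.order:
        raise ValueError("insert requires a seeded queue (see candidate_queues)")
    s_in = premise.subject in queue.positions
    o_in = premise.obj in queue.positions
    vx, vy = premise.relation.vec
    if s_in and o_in:
        out = queue.copy()
        got = out.summed_vector(premise.obj, premise.subject)
        if (_sign(got[0]), _sign(got[1])) != (vx, vy):
            out.consistent = False
        return out
    if not s_in and not o_in:
        raise KeyError("both premise terms are new; defer this premise")
    if o_in:
        new, ref, d = premise.subject, premise.obj, (vx, vy)
    else:
        new, ref, d = premise.obj, premise.subject, (-vx, -vy)
    out = queue.copy()
    g = out.queue_direction(ref)
    dot = d[0] * g[0] + d[1] * g[1]
    rx, ry = out.positions[ref]
    out.positions[new] = (rx + d[0], ry + d[1])
    if dot < 0:
        i = out.order.index(ref)
        out.order.insert(i, new)
        out.raw_links.insert(i, (-d[0], -d[1]))  # link new -> ref
        out.cost += costs.cost_create
        if i > 0:
            # the link that used to enter ref must be severed
            out.cost += costs.cost_break
    else:
        out.order.append(new)
        out.raw_links.append(d)
        out.cost += costs.cost_create
    return out


def insert_1d(queue: VerbalQueue, premise: Premise, costs: CostModel = CostModel()) -> VerbalQueue:
    """1-D insertion (identical machinery; kept as a named entry point)."""
    return insert_premise(queue, premise, costs)


def insert_cardinal(
    queue: VerbalQueue, premise: Premise, costs: CostModel = CostModel()
) -> VerbalQueue:
    """Cardinal insertion with the >90-degree (negative dot product) rule."""
    return insert_premise(queue, premise, costs)


@lru_cache(maxsize=16384)
def _preferred_cached(
    premises: Tuple[Premise, ...], costs: CostModel
) -> VerbalQueue:
    if not premises:
        raise ValueError("at least one premise required")
    candidates = list(candidate_queues(premises[0], costs))
    pending = list(premises[1:])
    while pending:
        progressed = False
        for premise in list(pending):
            terms = set(premise.terms())
            if terms & set(candidates[0].positions):
                candidates = [insert_premise(q, premise, costs) for q in candidates]
                pending.remove(premise)
                progressed = True
        if not progressed:
            raise ValueError("premises are not connectable into one queue")
    best = min(candidates, key=lambda q: q.cost)
    # tie: the left-to-right search preference keeps the first orientation
    for q in candidates:
        if q.cost == best.cost:
            return q
    return best


def preferred_queue(
    premises: Sequence[Premise], costs: CostModel = CostModel()
) -> VerbalQueue:
    """The cheapest candidate queue; ties keep the first orientation."""
    return _preferred_cached(tuple(premises), costs)


def conclude(
    queue: VerbalQueue,
    subject: str,
    obj: str,
    vocabulary: str,
    fallback: str = "incident-link",
) -> Tuple[Optional[Relation], bool]:
    """Relation of ``subject`` relative to ``obj`` read off the queue.

    Returns ``(relation, determinate)``.  A zero summed vector triggers the
    forced-choice fallback: decode the raw encoding of the single link
    incident to the subject term (``fallback="incident-link"``), or report
    indeterminate (``fallback="none"``).
    """
    for t in (subject, obj):
        if t not in queue.positions:
            raise KeyError(f"term not in queue: {t!r}")
    sx, sy = queue.summed_vector(obj, subject)  # pos(subject) - pos(obj)
    vec = (_sign(sx), _sign(sy))
    if vec != (0, 0):
        return relation_from_vec(vec, vocabulary), True
    if fallback == "incident-link":
        enc = queue.direction_at(subject)
        i = queue.order.index(subject)
        if i == len(queue.order) - 1:
            # the incident link points toward subject: keep its direction
            vec = (_sign(enc[0]), _sign(enc[1]))
        else:
            vec = (-_sign(enc[0]), -_sign(enc[1]))
        if vec == (0, 0):
            return None, False
        return relation_from_vec(vec, vocabulary), False
    return None, False


def predict(
    problem: Problem, costs: CostModel = CostModel(), rng=None
):
    """VerbalReasoner's response to a problem.

    Verification: accept iff every conclusion assertion agrees with the
    preferred queue's summed positions (zero-information assertions are
    rejected).  Single choice: conclude the queried relation, using the
    forced-choice fallback on fully indeterminate problems.
    """
    queue = preferred_queue(problem.premises, costs)
    if problem.task_type == "single_choice":
        assert problem.choices is not None
        subject, obj = problem.choices[0].subject, problem.choices[0].obj
        rel, _ = conclude(queue, subject, obj, problem.vocabulary)
        if rel is None:
            if rng is not None:
                return problem.choices[rng.integers(len(problem.choices))]
            return problem.choices[0]
        for c in problem.choices:
            if c.relation == rel:
                return c
        return problem.choices[0]
    assert problem.conclusion is not None
    if not queue.consistent:
        return False
    for assertion in problem.conclusion:
        if assertion.subject not in queue.positions or assertion.obj not in queue.positions:
            return False
        sx, sy = queue.summed_vector(assertion.obj, assertion.subject)
        if (_sign(sx), _sign(sy)) != assertion.relation.vec:
            return False
    return True
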