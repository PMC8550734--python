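"""Ground-truth relational reasoning: composition, model enumeration, closure.

This module is the logical backbone of the package.  It provides

* :func:`compose` — qualitative composition of two relations under the
  exact-axis semantics (per axis, the signed constraints add; opposite signs
  leave the axis unconstrained),
* :func:`enumerate_models` — the finite set of qualitative mental models of a
  premise set (distinct integer cells, canonicalized by per-axis rank order),
* :func:`verify` — valid / contradicted / indeterminate status of a putative
  conclusion, and
* :func:`closure_table` — a transitive-closure constraint table, the engine of
  the TransitiveClosure baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

from .relations import (
    Premise,
    Relation,
    VocabularyError,
    VOCAB_1D,
    VOCAB_CARDINAL,
    converse,
    encode_relation,
)

__all__ = [
    "MentalModel",
    "ClosureTable",
    "compose",
    "enumerate_models",
    "verify",
    "satisfiable",
    "possible_relations",
    "closure_table",
]

Vec = Tuple[int, int]


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


@dataclass(frozen=True)
class MentalModel:
    """A qualitative spatial arrangement: term -> integer grid cell.

    Models are compared by their per-axis rank-order pattern, which makes the
    representation translation- and scale-free.
    """

    terms: Tuple[str, ...]
    coords: Tuple[Vec, ...]  # aligned with ``terms``

    def position(self, term: str) -> Vec:
        try:
            return self.coords[self.terms.index(term)]
        except ValueError:
            raise KeyError(f"unknown term: {term!r}") from None

    def holds(self, premise: Premise) -> bool:
        sx, sy = self.position(premise.subject)
        ox, oy = self.position(premise.obj)
        return (_sign(sx - ox), _sign(sy - oy)) == premise.relation.vec

    def relation_between(self, subject: str, obj: str, vocabulary: str) -> Optional[Relation]:
        """The relation the model exhibits between two terms, if nameable."""
        from .relations import relation_from_vec

        sx, sy = self.position(subject)
        ox, oy = self.position(obj)
        vec = (_sign(sx - ox), _sign(sy - oy))
        try:
            return relation_from_vec(vec, vocabulary)
        except VocabularyError:
            return None

    def rank_pattern(self) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
        """Per-axis dense rank of each term; the canonical identity key."""
        return (
            _dense_ranks(tuple(c[0] for c in self.coords)),
            _dense_ranks(tuple(c[1] for c in self.coords)),
        )

    def axis_order(self, axis: int = 0) -> Tuple[str, ...]:
        """Terms sorted by one axis (ties broken by the other axis)."""
        other = 1 - axis
        return tuple(
            t
            for t, _ in sorted(
                zip(self.terms, self.coords),
                key=lambda tc: (tc[1][axis], tc[1][other]),
            )
        )


def _dense_ranks(values: Tuple[int, ...]) -> Tuple[int, ...]:
    order = sorted(set(values))
    rank = {v: i for i, v in enumerate(order)}
    return tuple(rank[v] for v in values)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def _axis_sum(s1: int, s2: int) -> Optional[int]:
    """Sum of two signed axis constraints; ``None`` = unconstrained."""
    if s1 == 0:
        return s2
    if s2 == 0:
        return s1
    if s1 == s2:
        return s1
    return None  # opposite signs: any sign possible


def compose(r1: Relation, r2: Relation) -> FrozenSet[Relation]:
    """Relations possible between A and C given "A r1 B" and "B r2 C".

    Componentwise: ``pos(A)-pos(C) = (pos(A)-pos(B)) + (pos(B)-pos(C))``.
    An axis whose two constraints agree in sign (or where one is zero) is
    determined; opposite signs leave it unconstrained.  The result is every
    vocabulary relation matching all determined axes.
    """
    if r1.vocabulary != r2.vocabulary:
        raise VocabularyError(
            f"cannot compose across vocabularies: {r1.vocabulary} vs {r2.vocabulary}"
        )
    dx = _axis_sum(r1.vec[0], r2.vec[0])
    dy = _axis_sum(r1.vec[1], r2.vec[1])
    table = VOCAB_1D if r1.vocabulary == "1D" else VOCAB_CARDINAL
    out = []
    for name, vec in table.items():
        if dx is not None and vec[0] != dx:
            continue
        if dy is not None and vec[1] != dy:
            continue
        out.append(encode_relation(name))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Model enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _weak_orderings(n: int) -> Tuple[Tuple[int, ...], ...]:
    """All dense-rank patterns (orderings with ties) of ``n`` items."""
    seen = set()
    for f in itertools.product(range(n), repeat=n):
        seen.add(_dense_ranks(f))
    return tuple(sorted(seen))


def _terms_in_order(premises: Sequence[Premise]) -> Tuple[str, ...]:
    out: list[str] = []
    for p in premises:
        for t in p.terms():
            if t not in out:
                out.append(t)
    return tuple(out)


def _axis_patterns(
    n: int, constraints: Sequence[Tuple[int, int, int]]
) -> Tuple[Tuple[int, ...], ...]:
    """Weak orderings of ``n`` items satisfying ``sign(r[i]-r[j]) == s``."""
    out = []
    for ranks in _weak_orderings(n):
        if all(_sign(ranks[i] - ranks[j]) == s for i, j, s in constraints):
            out.append(ranks)
    return tuple(out)


@lru_cache(maxsize=4096)
def _enumerate_cached(premises: Tuple[Premise, ...]) -> Tuple[MentalModel, ...]:
    terms = _terms_in_order(premises)
    n = len(terms)
    if n == 0:
        return ()
    if n > 6:
        raise ValueError("model enumeration supports at most 6 terms")
    index = {t: i for i, t in enumerate(terms)}
    cons_x = []
    cons_y = []
    for p in premises:
        i, j = index[p.subject], index[p.obj]
        cons_x.append((i, j, p.relation.vec[0]))
        cons_y.append((i, j, p.relation.vec[1]))
    pats_x = _axis_patterns(n, cons_x)
    pats_y = _axis_patterns(n, cons_y)
    models = []
    for rx in pats_x:
        for ry in pats_y:
            # distinct cells: no two terms may share both ranks
            cells = set(zip(rx, ry))
            if len(cells) < n:
                continue
            coords = tuple(
                (rx[i] - rx[0], ry[i] - ry[0]) for i in range(n)
            )  # first term at the origin
            models.append(MentalModel(terms=terms, coords=coords))
    return tuple(models)


def enumerate_models(
    premises: Sequence[Premise], grid_half_width: Optional[int] = None
) -> Tuple[MentalModel, ...]:
    """All qualitative models of the premises (distinct integer cells).

    Enumeration is over per-axis rank-order patterns, which is exactly the
    canonical form models are deduplicated by; every lattice placement within
    any sufficiently large grid reduces to one of these patterns, so the
    result is complete and placement-scale-free.  ``grid_half_width`` is
    accepted for interface compatibility; ranks always fit the default grid
    (number of terms + 1).
    """
    del grid_half_width
    return _enumerate_cached(tuple(premises))


def satisfiable(premises: Sequence[Premise]) -> bool:
    """True iff the premises admit at least one model."""
    return bool(enumerate_models(premises))


def verify(premises: Sequence[Premise], conclusion: Premise) -> str:
    """Status of a conclusion: ``"valid"``, ``"contradicted"``, ``"indeterminate"``.

    Valid iff the conclusion holds in every model of the premises,
    contradicted iff in none, indeterminate otherwise.  Premises admitting no
    model at all make every conclusion ``"contradicted"``.
    """
    models = enumerate_models(premises)
    known = set()
    for p in premises:
        known.update(p.terms())
    for t in conclusion.terms():
        if t not in known:
            raise KeyError(f"conclusion term not in premises: {t!r}")
    if not models:
        return "contradicted"
    holds = [m.holds(conclusion) for m in models]
    if all(holds):
        return "valid"
    if not any(holds):
        return "contradicted"
    return "indeterminate"


def possible_relations(
    premises: Sequence[Premise], subject: str, obj: str
) -> FrozenSet[Relation]:
    """Relations between two terms realized by at least one model."""
    vocabulary = premises[0].relation.vocabulary
    out = set()
    for m in enumerate_models(premises):
        r = m.relation_between(subject, obj, vocabulary)
        if r is not None:
            out.add(r)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Transitive-closure constraint table
# ---------------------------------------------------------------------------


@dataclass
class ClosureTable:
    """Pair -> set of relations still possible given the premises.

    Built by seeding premise pairs with their stated relation (full
    vocabulary elsewhere) and repeatedly applying the transitive rule
    ``R(X,Z) ⊆ compose(R(X,Y), R(Y,Z))`` to a fixpoint.  Converse pairs are
    kept mirrored throughout.
    """

    terms: Tuple[str, ...]
    vocabulary: str
    table: Dict[Tuple[str, str], FrozenSet[Relation]]

    def relations(self, subject: str, obj: str) -> FrozenSet[Relation]:
        return self.table[(subject, obj)]

    def status(self, subject: str, obj: str) -> str:
        rels = self.table[(subject, obj)]
        if not rels:
            return "contradicted"
        return "determinate" if len(rels) == 1 else "indeterminate"

    @property
    def consistent(self) -> bool:
        return all(self.table.values())


def _compose_sets(
    a: FrozenSet[Relation], b: FrozenSet[Relation]
) -> FrozenSet[Relation]:
    out: set[Relation] = set()
    for r1 in a:
        for r2 in b:
            out |= compose(r1, r2)
    return frozenset(out)


def closure_table(premises: Sequence[Premise]) -> ClosureTable:
    """Propagate premise constraints to a path-consistent fixpoint."""
    terms = _terms_in_order(premises)
    vocabulary = premises[0].relation.vocabulary
    table_names = VOCAB_1D if vocabulary == "1D" else VOCAB_CARDINAL
    full = frozenset(encode_relation(n) for n in table_names)
    table: Dict[Tuple[str, str], FrozenSet[Relation]] = {
        (a, b): full for a in terms for b in terms if a != b
    }
    for p in premises:
        table[(p.subject, p.obj)] &= frozenset([p.relation])
        table[(p.obj, p.subject)] &= frozenset([converse(p.relation)])
    changed = True
    while changed:
        changed = False
        for x, y, z in itertools.permutations(terms, 3):
            narrowed = table[(x, z)] & _compose_sets(table[(x, y)], table[(y, z)])
            if narrowed != table[(x, z)]:
                table[(x, z)] = narrowed
                table[(z, x)] = frozenset(converse(r) for r in narrowed)
                changed = True
    return ClosureTable(terms=terms, vocabulary=vocabulary, table=table)
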