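"""Qualitative spatial vocabulary, vector encodings, and the task-string dialect.

Two disjoint vocabularies are supported: the one-dimensional relations
``left``/``right`` used in tabletop-style problems, and the eight cardinal
directions (``north`` .. ``north-west``).  Every relation carries an integer
sign vector ``(dx, dy)`` in a shared frame: x grows rightward/eastward and
y grows northward.  A premise "X REL Y" asserts that the componentwise sign
of ``position(X) - position(Y)`` equals the relation's vector exactly
(each relation constrains *both* axes; "north" implies dx = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "Relation",
    "Premise",
    "Problem",
    "VocabularyError",
    "ParseError",
    "VOCAB_1D",
    "VOCAB_CARDINAL",
    "encode_relation",
    "relation_from_vec",
    "converse",
    "parse_premise",
    "format_premise",
    "parse_task",
    "format_task",
    "parse_assertions",
    "format_assertions",
]

Vec = Tuple[int, int]

#: name -> sign vector for the 1-D (tabletop) vocabulary
VOCAB_1D: dict[str, Vec] = {"left": (-1, 0), "right": (1, 0)}

#: name -> sign vector for the eight cardinal directions
VOCAB_CARDINAL: dict[str, Vec] = {
    "north": (0, 1),
    "north-east": (1, 1),
    "east": (1, 0),
    "south-east": (1, -1),
    "south": (0, -1),
    "south-west": (-1, -1),
    "west": (-1, 0),
    "north-west": (-1, 1),
}

_VOCABS: dict[str, dict[str, Vec]] = {"1D": VOCAB_1D, "cardinal": VOCAB_CARDINAL}


class VocabularyError(ValueError):
    """Unknown relation name or mixed-vocabulary use."""


class ParseError(ValueError):
    """Malformed task string or CSV field."""


@dataclass(frozen=True, order=True)
class Relation:
    """A qualitative direction with its integer sign-vector encoding."""

    name: str
    vec: Vec
    vocabulary: str  # "1D" or "cardinal"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def vocabulary_of(name: str) -> str:
    """Return the vocabulary a relation name belongs to."""
    if name in VOCAB_1D:
        return "1D"
    if name in VOCAB_CARDINAL:
        return "cardinal"
    raise VocabularyError(f"unknown relation name: {name!r}")


def encode_relation(name: str, vocabulary: Optional[str] = None) -> Relation:
    """Build a :class:`Relation` from its name.

    The two vocabularies are disjoint namespaces, so the vocabulary can be
    inferred from the name alone; passing ``vocabulary`` adds a consistency
    check.
    """
    voc = vocabulary_of(name)
    if vocabulary is not None and vocabulary != voc:
        raise VocabularyError(f"{name!r} is not in the {vocabulary!r} vocabulary")
    return Relation(name=name, vec=_VOCABS[voc][name], vocabulary=voc)


def relation_from_vec(vec: Vec, vocabulary: str) -> Relation:
    """Decode a sign vector back into the named relation of a vocabulary."""
    try:
        table = _VOCABS[vocabulary]
    except KeyError:
        raise VocabularyError(f"unknown vocabulary: {vocabulary!r}") from None
    for name, v in table.items():
        if v == vec:
            return Relation(name=name, vec=v, vocabulary=vocabulary)
    raise VocabularyError(f"no {vocabulary} relation has vector {vec}")


def converse(r: Relation) -> Relation:
    """The relation with the mirrored vector, in the same vocabulary.

    ``converse`` is an involution: ``converse(converse(r)) == r``.
    """
    return relation_from_vec((-r.vec[0], -r.vec[1]), r.vocabulary)


@dataclass(frozen=True, order=True)
class Premise:
    """An assertion "subject RELATION object" between two distinct terms."""

    relation: Relation
    subject: str
    obj: str

    def __post_init__(self) -> None:
        if self.subject == self.obj:
            raise ParseError(f"self-referential premise: {self.subject!r}")

    def terms(self) -> Tuple[str, str]:
        return (self.subject, self.obj)

    def converse_form(self) -> "Premise":
        """The logically equivalent assertion with swapped terms."""
        return Premise(converse(self.relation), self.obj, self.subject)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.subject} {self.relation.name} {self.obj}"


@dataclass(frozen=True)
class Problem:
    """An ordered premise list plus task type and response options.

    Verification problems carry a putative conclusion of one or more
    assertions (four for arrangement-verification items); single-choice
    problems carry at least two candidate conclusions over terms occurring
    in the premises.
    """

    premises: Tuple[Premise, ...]
    task_type: str  # "verification" or "single_choice"
    conclusion: Optional[Tuple[Premise, ...]] = None
    choices: Optional[Tuple[Premise, ...]] = None
    vocabulary: str = field(default="1D")

    def __post_init__(self) -> None:
        if self.task_type not in ("verification", "single_choice"):
            raise ParseError(f"unknown task type: {self.task_type!r}")
        vocs = {p.relation.vocabulary for p in self.premises}
        for group in (self.conclusion or ()), (self.choices or ()):
            vocs |= {p.relation.vocabulary for p in group}
        if len(vocs) > 1:
            raise VocabularyError(f"mixed vocabularies in one problem: {sorted(vocs)}")
        if vocs and self.vocabulary not in vocs:
            object.__setattr__(self, "vocabulary", vocs.pop())
        if self.task_type == "verification":
            if not self.conclusion:
                raise ParseError("verification problem requires a conclusion")
        else:
            if not self.choices or len(self.choices) < 2:
                raise ParseError("single-choice problem requires >= 2 choices")
            terms = self.term_set()
            for c in self.choices:
                if c.subject not in terms or c.obj not in terms:
                    raise ParseError(
                        f"choice term not in premises: {c.subject} / {c.obj}"
                    )

    def term_set(self) -> set[str]:
        out: set[str] = set()
        for p in self.premises:
            out.update(p.terms())
        return out


# ---------------------------------------------------------------------------
# Task-string dialect:  premises joined by "/", each "relation;subject;object";
# choice lists joined by "|".
# ---------------------------------------------------------------------------


def parse_premise(s: str) -> Premise:
    parts = s.split(";")
    if len(parts) != 3 or not all(parts):
        raise ParseError(f"malformed premise triple: {s!r}")
    rel, subject, obj = parts
    return Premise(encode_relation(rel), subject, obj)


def format_premise(p: Premise) -> str:
    return f"{p.relation.name};{p.subject};{p.obj}"


def parse_assertions(s: str) -> Tuple[Premise, ...]:
    """Parse a "/"-joined list of assertions."""
    if not s:
        raise ParseError("empty assertion list")
    return tuple(parse_premise(part) for part in s.split("/"))


def format_assertions(premises: Iterable[Premise]) -> str:
    return "/".join(format_premise(p) for p in premises)


def parse_task(
    task: str,
    task_type: str = "verification",
    conclusion: Optional[str] = None,
    choices: Optional[str] = None,
) -> Problem:
    """Parse a task string (optionally with conclusion/choice strings).

    ``parse_task(format_task(p), ...)`` round-trips to an equal problem.
    """
    premises = parse_assertions(task)
    parsed_conclusion = parse_assertions(conclusion) if conclusion else None
    parsed_choices: Optional[Tuple[Premise, ...]] = None
    if choices:
        parsed_choices = tuple(
            parse_premise(c) if "/" not in c else parse_assertions(c)[0]
            for c in choices.split("|")
        )
    if task_type == "verification" and parsed_conclusion is None and choices:
        # CCOBRA-style files carry the putative conclusion in the choices column.
        parsed_conclusion = parse_assertions(choices.split("|")[0])
        parsed_choices = None
    return Problem(
        premises=premises,
        task_type=task_type,
        conclusion=parsed_conclusion,
        choices=parsed_choices,
    )


def format_task(p: Problem) -> str:
    """The premise part of the task string."""
    return format_assertions(p.premises)


def format_choices(p: Problem) -> str:
    """The choices/conclusion column for the CSV dialect."""
    if p.task_type == "verification":
        assert p.conclusion is not None
        return format_assertions(p.conclusion)
    assert p.choices is not None
    return "|".join(format_premise(c) for c in p.choices)
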