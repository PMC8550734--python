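"""Reference models bracketing cognitive-model performance.

* ``RandomModel`` — uniform over the response options (lower bound),
* ``MFAModel`` — most frequent answer in the training data (aggregate-level
  ceiling for participant-independent models),
* ``TransitiveClosureModel`` — pure logic via the closure/enumeration oracle;
  on multi-option problems it draws uniformly among the logically consistent
  options,
* ``BestModelBaseline`` — picks the best-fitting pool model per participant,
* ``OptimalModel`` — correct on a trial iff *any* pool model is correct
  (the union oracle; an upper bound on what the pool could explain).
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import oracle
from .io import Dataset, Trial
from .relations import Premise, Problem, format_premise, format_task

__all__ = [
    "Model",
    "RandomModel",
    "MFAModel",
    "TransitiveClosureModel",
    "BestModelBaseline",
    "OptimalModel",
    "problem_key",
    "response_key",
]


class Model:
    """Uniform interface for everything the coverage harness evaluates.

    A fresh instance is used per (model, participant).  ``pre_train`` sees all
    *other* participants' data, ``pre_train_person`` the target participant's
    own trials (the coverage setting), then ``predict`` is called per trial in
    recorded sequence order.  ``adapt`` is the post-prediction feedback hook of
    the evaluation protocol; it is defined but unused in coverage runs.
    """

    name: str = "model"
    needs_truth: bool = False

    def pre_train(self, dataset: Dataset) -> None:  # noqa: B027
        pass

    def pre_train_person(self, trials: Sequence[Trial]) -> None:  # noqa: B027
        pass

    def predict(self, problem: Problem, rng: np.random.Generator):
        raise NotImplementedError

    def adapt(self, problem: Problem, truth) -> None:  # noqa: B027
        pass


def problem_key(problem: Problem) -> str:
    """Canonical identity of a problem; premise order is preserved because
    presentation order is part of the problem (the continuity effect)."""
    from .relations import format_choices

    return f"{format_task(problem)}::{problem.task_type}::{format_choices(problem)}"


def response_key(response) -> str:
    if isinstance(response, bool):
        return str(response)
    return format_premise(response)


def _options(problem: Problem) -> List:
    if problem.task_type == "verification":
        return [True, False]
    assert problem.choices is not None
    return list(problem.choices)


class RandomModel(Model):
    name = "random"

    def predict(self, problem: Problem, rng: np.random.Generator):
        options = _options(problem)
        return options[int(rng.integers(len(options)))]


class MFAModel(Model):
    """Most-frequent-answer table built from the pre-train data."""

    name = "mfa"

    def __init__(self) -> None:
        self.table: Dict[str, Counter] = {}

    def pre_train(self, dataset: Dataset) -> None:
        for trial in dataset:
            if trial.response is None:
                continue
            self.table.setdefault(problem_key(trial.problem), Counter())[
                response_key(trial.response)
            ] += 1

    def predict(self, problem: Problem, rng: np.random.Generator):
        counts = self.table.get(problem_key(problem))
        options = _options(problem)
        if not counts:
            return options[int(rng.integers(len(options)))]
        # argmax; ties broken lexicographically on the encoded response
        best = min(counts, key=lambda k: (-counts[k], k))
        for option in options:
            if response_key(option) == best:
                return option
        return options[int(rng.integers(len(options)))]


class TransitiveClosureModel(Model):
    """Logically correct responder driven by the relational oracle."""

    name = "closure"

    def predict(self, problem: Problem, rng: np.random.Generator):
        if problem.task_type == "verification":
            assert problem.conclusion is not None
            return oracle.satisfiable(tuple(problem.premises) + tuple(problem.conclusion))
        assert problem.choices is not None
        consistent = [
            c
            for c in problem.choices
            if oracle.verify(problem.premises, c) != "contradicted"
        ]
        if not consistent:
            consistent = list(problem.choices)
        return consistent[int(rng.integers(len(consistent)))]


class BestModelBaseline(Model):
    """Per-participant argmax over a pool of cognitive models.

    The pool is given as (name, factory) pairs; accuracy ties break by pool
    order.  Pool members receive the same pre-train / pre-train-person data.
    """

    name = "best"

    def __init__(self, pool: Sequence[Tuple[str, Callable[[], Model]]]):
        self.pool = list(pool)
        self._pretrain: Optional[Dataset] = None
        self.selected: Optional[Model] = None
        self.selected_name: Optional[str] = None

    def pre_train(self, dataset: Dataset) -> None:
        self._pretrain = dataset

    def pre_train_person(self, trials: Sequence[Trial]) -> None:
        best_score = -1
        for name, factory in self.pool:
            member = factory()
            if self._pretrain is not None:
                member.pre_train(self._pretrain)
            member.pre_train_person(trials)
            rng = np.random.default_rng(0)  # scoring stream, fixed per fit
            score = sum(
                1
                for t in trials
                if t.response is not None
                and member.predict(t.problem, rng) == t.response
            )
            if score > best_score:
                best_score = score
                self.selected, self.selected_name = member, name

    def predict(self, problem: Problem, rng: np.random.Generator):
        if self.selected is None:
            raise RuntimeError("BestModel requires pre_train_person before predict")
        return self.selected.predict(problem, rng)


class OptimalModel(Model):
    """Union oracle over a model pool, scored at the level of single trials.

    Its prediction equals the true response whenever at least one pool member
    predicts it; otherwise it returns the first member's prediction.  This
    realizes "correct iff some pool model is correct" inside the ordinary
    prediction interface (it therefore needs the truth at prediction time).
    """

    name = "optimal"
    needs_truth = True

    def __init__(self, pool: Sequence[Tuple[str, Callable[[], Model]]]):
        self.pool = list(pool)
        self.members: List[Model] = []

    def pre_train(self, dataset: Dataset) -> None:
        self.members = [factory() for _, factory in self.pool]
        for m in self.members:
            m.pre_train(dataset)

    def pre_train_person(self, trials: Sequence[Trial]) -> None:
        if not self.members:
            self.members = [factory() for _, factory in self.pool]
        for m in self.members:
            m.pre_train_person(trials)

    def predict(self, problem: Problem, rng: np.random.Generator, truth=None):
        predictions = [m.predict(problem, rng) for m in self.members]
        if truth is not None and any(p == truth for p in predictions):
            return truth
        return predictions[0]
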