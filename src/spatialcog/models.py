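"""Adapters exposing the cognitive models through the evaluation interface,
plus the name registry used by the CLI and the default model pool."""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import prism as prism_mod
from . import spatial_reasoner as sr
from . import verbal as verbal_mod
from .baselines import (
    BestModelBaseline,
    MFAModel,
    Model,
    OptimalModel,
    RandomModel,
    TransitiveClosureModel,
)
from .io import Trial
from .relations import Problem

__all__ = [
    "SpatialReasonerModel",
    "PrismModel",
    "VerbalModel",
    "REGISTRY",
    "cognitive_pool",
    "make_model",
    "registered_names",
]


class SpatialReasonerModel(Model):
    """One SpatialReasoner variant; ``adapted`` fits the sub-variant per person."""

    def __init__(self, variant: str = "adapted"):
        if variant not in ("skeptical", "initial", "credulous", "adapted"):
            raise ValueError(f"unknown SpatialReasoner variant: {variant!r}")
        self.variant = variant
        self._fitted: Optional[str] = None
        self.name = f"sr-{variant}"

    def pre_train_person(self, trials: Sequence[Trial]) -> None:
        if self.variant == "adapted":
            self._fitted = sr.fit_adapted(
                [t for t in trials if t.response is not None]
            )

    def predict(self, problem: Problem, rng: np.random.Generator):
        variant = self._fitted or self.variant
        if variant == "adapted":
            variant = "skeptical"  # unfitted fallback (no person data seen)
        return sr.predict(problem, variant)


class PrismModel(Model):
    """PRISM with either fixed parameters or per-person grid-search fitting."""

    def __init__(self, params: Optional[prism_mod.PrismParams] = None, fit: bool = True):
        self.params = params or prism_mod.PrismParams("fff", 0)
        self.fit = fit and params is None
        self.name = "prism" if self.fit else (
            f"prism-{self.params.strategy}-{self.params.variation_depth}"
        )

    def pre_train_person(self, trials: Sequence[Trial]) -> None:
        if self.fit:
            self.params = prism_mod.fit([t for t in trials if t.response is not None])

    def predict(self, problem: Problem, rng: np.random.Generator):
        return prism_mod.predict(problem, self.params)


class VerbalModel(Model):
    """Verbal queue reasoner with configurable link costs."""

    name = "verbal"

    def __init__(self, costs: Optional[verbal_mod.CostModel] = None):
        self.costs = costs or verbal_mod.CostModel()

    def predict(self, problem: Problem, rng: np.random.Generator):
        return verbal_mod.predict(problem, self.costs, rng=None)


def cognitive_pool() -> List[Tuple[str, Callable[[], Model]]]:
    """The default pool BestModel/Optimal select from."""
    return [
        ("prism", lambda: PrismModel()),
        ("verbal", lambda: VerbalModel()),
        ("sr-skeptical", lambda: SpatialReasonerModel("skeptical")),
        ("sr-initial", lambda: SpatialReasonerModel("initial")),
        ("sr-credulous", lambda: SpatialReasonerModel("credulous")),
        ("sr-adapted", lambda: SpatialReasonerModel("adapted")),
        ("closure", lambda: TransitiveClosureModel()),
    ]


REGISTRY: Dict[str, Callable[[], Model]] = {
    "random": RandomModel,
    "mfa": MFAModel,
    "closure": TransitiveClosureModel,
    "best": lambda: BestModelBaseline(cognitive_pool()),
    "optimal": lambda: OptimalModel(cognitive_pool()),
    "prism": lambda: PrismModel(),
    "verbal": lambda: VerbalModel(),
    "sr-skeptical": lambda: SpatialReasonerModel("skeptical"),
    "sr-initial": lambda: SpatialReasonerModel("initial"),
    "sr-credulous": lambda: SpatialReasonerModel("credulous"),
    "sr-adapted": lambda: SpatialReasonerModel("adapted"),
}


def registered_names() -> List[str]:
    return sorted(REGISTRY)


def make_model(name: str) -> Model:
    try:
        factory = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: {', '.join(registered_names())}"
        ) from None
    return factory()
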