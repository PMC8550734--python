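"""Individual-level coverage evaluation: phases, scoring, and summaries.

In the *coverage* setting a model is shown, before predicting, exactly the
problem-response pairs it will be asked to predict: for each participant the
pool first receives every *other* participant's trials (``pre_train``), then
the target participant's own full trial set (``pre_train_person``), and is
then scored on that participant's trials one by one in recorded presentation
order.  A reasoner is "covered" by a model if some parameterization of the
model reproduces their responses.  The post-prediction ``adapt`` feedback
phase exists in the interface but is disabled here.

Summary statistics follow the benchmark convention: per-model median and MAD
(raw median absolute deviation, percent scale) of per-participant accuracies,
plus the asymmetric co-optimality matrix (given model i was correct on a
trial, how often was model j also correct).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .baselines import Model
from .io import Dataset, Trial

__all__ = ["EvaluationConfig", "EvaluationResult", "run_coverage", "co_optimality", "summarize"]


@dataclass
class EvaluationConfig:
    """What to evaluate and how.

    ``models`` maps display name -> zero-argument factory producing a fresh
    model instance per participant.  ``seed`` drives one run-level random
    stream, split per (model, participant) so participant order cannot change
    any result.
    """

    models: Sequence[Tuple[str, Callable[[], Model]]]
    seed: int = 0
    pre_train: bool = True
    pre_train_person: bool = True


@dataclass
class EvaluationResult:
    """Long-format predictions plus derived accuracy tables."""

    predictions: pd.DataFrame  # model, participant, sequence, prediction, truth, correct
    accuracies: pd.DataFrame  # model, participant, n_trials, accuracy

    def accuracy_of(self, model: str, participant: str) -> float:
        sel = self.accuracies[
            (self.accuracies.model == model)
            & (self.accuracies.participant == participant)
        ]
        return float(sel.accuracy.iloc[0])

    def participant_accuracies(self, model: str) -> pd.Series:
        sel = self.accuracies[self.accuracies.model == model]
        return sel.set_index("participant").accuracy


def _participant_rng(seed: int, model_name: str, participant: str) -> np.random.Generator:
    # deterministic per (model, participant), independent of iteration order
    # (zlib.crc32 is stable across processes, unlike the builtin hash)
    digest = zlib.crc32(f"{model_name}::{participant}".encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def run_coverage(dataset: Dataset, config: EvaluationConfig) -> EvaluationResult:
    """Evaluate every configured model on every participant."""
    rows: List[dict] = []
    from .baselines import response_key

    for participant in dataset.participants:
        person_trials = dataset.for_participant(participant)
        person_trials = tuple(t for t in person_trials if t.response is not None)
        if not person_trials:
            warnings.warn(f"participant {participant!r} has no scored trials; skipped")
            continue
        others = dataset.excluding(participant)
        for model_name, factory in config.models:
            model = factory()
            rng = _participant_rng(config.seed, model_name, participant)
            if config.pre_train:
                model.pre_train(others)
            if config.pre_train_person:
                model.pre_train_person(person_trials)
            for trial in person_trials:
                if model.needs_truth:
                    prediction = model.predict(trial.problem, rng, truth=trial.response)
                else:
                    prediction = model.predict(trial.problem, rng)
                rows.append(
                    {
                        "model": model_name,
                        "participant": participant,
                        "sequence": trial.sequence,
                        "condition": trial.condition,
                        "prediction": response_key(prediction),
                        "truth": response_key(trial.response),
                        "correct": prediction == trial.response,
                    }
                )
    predictions = pd.DataFrame(rows)
    if predictions.empty:
        raise ValueError("no scored trials in dataset")
    accuracies = (
        predictions.groupby(["model", "participant"], sort=False)
        .agg(n_trials=("correct", "size"), accuracy=("correct", "mean"))
        .reset_index()
    )
    return EvaluationResult(predictions=predictions, accuracies=accuracies)


def co_optimality(result: EvaluationResult, model_i: str, model_j: str) -> Optional[float]:
    """Among trials model_i got right, the fraction model_j also got right.

    Returns ``None`` when model_i was never correct.  The matrix formed by
    all ordered pairs has a unit diagonal and need not be symmetric.
    """
    df = result.predictions
    a = df[df.model == model_i].set_index(["participant", "sequence"]).correct
    b = df[df.model == model_j].set_index(["participant", "sequence"]).correct
    joined = pd.concat([a.rename("i"), b.rename("j")], axis=1, join="inner")
    hits_i = joined[joined.i]
    if hits_i.empty:
        return None
    return float(hits_i.j.mean())


def co_optimality_matrix(result: EvaluationResult) -> pd.DataFrame:
    names = list(dict.fromkeys(result.predictions.model))
    data = {
        mi: [co_optimality(result, mi, mj) for mj in names] for mi in names
    }
    return pd.DataFrame(data, index=names).T  # rows: model_i, columns: model_j


def summarize(result: EvaluationResult, by_condition: bool = True) -> pd.DataFrame:
    """Per-model median and MAD of participant accuracies, percent scale.

    MAD is the raw median absolute deviation times 100 (no consistency
    factor), matching the benchmark's integer-style dispersion reports.
    When trials carry conditions, per-condition rows are added.
    """
    def _rows(acc: pd.DataFrame, condition: str) -> List[dict]:
        out = []
        for model, group in acc.groupby("model", sort=False):
            values = group.accuracy.to_numpy()
            med = float(np.median(values))
            mad = float(np.median(np.abs(values - med)))
            out.append(
                {
                    "model": model,
                    "condition": condition,
                    "n_participants": len(values),
                    "median_pct": 100.0 * med,
                    "mad_pct": 100.0 * mad,
                }
            )
        return out

    rows = _rows(result.accuracies, "all")
    if by_condition and result.predictions.condition.astype(bool).any():
        for condition, sub in result.predictions.groupby("condition", sort=False):
            if not condition:
                continue
            acc = (
                sub.groupby(["model", "participant"], sort=False)
                .agg(accuracy=("correct", "mean"))
                .reset_index()
            )
            rows.extend(_rows(acc, str(condition)))
    return pd.DataFrame(rows)
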