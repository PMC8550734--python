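"""Dataset containers and the CSV dialect readers/writers.

A dataset is a mapping participant -> ordered trials.  The on-disk format is
a comma-separated UTF-8 file with header columns ``id, sequence, task,
response_type, choices, response, condition``:

* ``task`` — premises joined by ``/``, each ``relation;subject;object``
* ``response_type`` — ``verify`` or ``single-choice``
* ``choices`` — for verification the putative conclusion assertion(s); for
  single choice the candidate conclusions joined by ``|``
* ``response`` — ``True``/``False`` for verification, a single premise triple
  for single choice

This is the dialect the published benchmark files of this task family use, so
external per-trial CSVs load with the same reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .relations import (
    ParseError,
    Premise,
    Problem,
    format_choices,
    format_premise,
    format_task,
    parse_assertions,
    parse_premise,
)

__all__ = ["Trial", "Dataset", "read_dataset", "write_dataset", "COLUMNS"]

COLUMNS = ["id", "sequence", "task", "response_type", "choices", "response", "condition"]

Response = Union[bool, Premise]

_RESPONSE_TYPE = {"verification": "verify", "single_choice": "single-choice"}
_TASK_TYPE = {v: k for k, v in _RESPONSE_TYPE.items()}


@dataclass(frozen=True)
class Trial:
    """One presented problem with the participant's recorded response."""

    participant: str
    sequence: int
    problem: Problem
    response: Optional[Response] = None
    condition: str = ""


@dataclass
class Dataset:
    """Participants -> ordered trials, in recorded sequence order."""

    trials: Dict[str, Tuple[Trial, ...]] = field(default_factory=dict)

    @property
    def participants(self) -> Tuple[str, ...]:
        return tuple(self.trials)

    def __len__(self) -> int:
        return sum(len(v) for v in self.trials.values())

    def __iter__(self):
        for trials in self.trials.values():
            yield from trials

    def for_participant(self, participant: str) -> Tuple[Trial, ...]:
        return self.trials[participant]

    def excluding(self, participant: str) -> "Dataset":
        """All other participants' trials (the pre-train split)."""
        return Dataset({p: t for p, t in self.trials.items() if p != participant})

    @staticmethod
    def from_trials(trials: Iterable[Trial]) -> "Dataset":
        by_participant: Dict[str, List[Trial]] = {}
        for t in trials:
            by_participant.setdefault(t.participant, []).append(t)
        out: Dict[str, Tuple[Trial, ...]] = {}
        for p, ts in by_participant.items():
            ts.sort(key=lambda t: t.sequence)
            seqs = [t.sequence for t in ts]
            if len(set(seqs)) != len(seqs):
                raise ParseError(f"duplicate sequence numbers for participant {p!r}")
            out[p] = tuple(ts)
        return Dataset(out)


def _format_response(problem: Problem, response: Optional[Response]) -> str:
    if response is None:
        return ""
    if problem.task_type == "verification":
        if not isinstance(response, bool):
            raise ParseError("verification response must be True/False")
        return str(response)
    if not isinstance(response, Premise):
        raise ParseError("single-choice response must be a premise triple")
    return format_premise(response)


def _parse_response(problem: Problem, raw: str, where: str) -> Optional[Response]:
    if raw == "" or raw is None:
        return None
    if problem.task_type == "verification":
        if raw not in ("True", "False"):
            raise ParseError(f"{where}: verification response must be True/False, got {raw!r}")
        return raw == "True"
    try:
        response = parse_premise(raw)
    except ParseError as e:
        raise ParseError(f"{where}: bad single-choice response: {e}") from None
    return response


def read_dataset(path: Union[str, Path]) -> Dataset:
    """Read a benchmark CSV; row-level validation names the offending row."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty dataset file: {path}")
        return Dataset()
    missing = [c for c in COLUMNS if c not in df.columns and c != "condition"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    trials: List[Trial] = []
    for idx, row in df.iterrows():
        where = f"{path} row {idx + 2}"  # header is row 1
        rtype = row["response_type"]
        if rtype not in _TASK_TYPE:
            raise ParseError(f"{where}: unknown response_type {rtype!r}")
        task_type = _TASK_TYPE[rtype]
        try:
            if task_type == "verification":
                problem = Problem(
                    premises=parse_assertions(row["task"]),
                    task_type=task_type,
                    conclusion=parse_assertions(row["choices"]),
                )
            else:
                problem = Problem(
                    premises=parse_assertions(row["task"]),
                    task_type=task_type,
                    choices=tuple(parse_premise(c) for c in row["choices"].split("|")),
                )
        except ParseError as e:
            raise ParseError(f"{where}: {e}") from None
        response = _parse_response(problem, row["response"], where)
        trials.append(
            Trial(
                participant=str(row["id"]),
                sequence=int(row["sequence"]),
                problem=problem,
                response=response,
                condition=str(row.get("condition", "")),
            )
        )
    return Dataset.from_trials(trials)


def write_dataset(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset in the benchmark CSV dialect (lossless round trip)."""
    rows = []
    for trial in dataset:
        rows.append(
            {
                "id": trial.participant,
                "sequence": trial.sequence,
                "task": format_task(trial.problem),
                "response_type": _RESPONSE_TYPE[trial.problem.task_type],
                "choices": format_choices(trial.problem),
                "response": _format_response(trial.problem, trial.response),
                "condition": trial.condition,
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
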