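"""Shared trial-log record type and its CSV dialect.

Every stage of the pipeline (task environments, synthetic agents, the loop
model, the scorers) exchanges data as lists of :class:`TrialRecord`, one
record per trial.  The on-disk form is a plain CSV with the header

    participant_id,task,trial,stimulus,response,correct,feedback,active_rule,rt

``stimulus`` is a string: for the card-sorting task it encodes the test card
as ``"<number>:<color>:<shape>"``; for the spatial-anticipation task it is
the (1-based) position of the currently filled disk.  ``response`` and
``correct`` are integer response indices; an out-of-bounds touch is stored
with the sentinel response ``0``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, List, Union

#: sentinel response value for touches outside the valid response locations
OUT_OF_BOUNDS = 0

CSV_HEADER = [
    "participant_id",
    "task",
    "trial",
    "stimulus",
    "response",
    "correct",
    "feedback",
    "active_rule",
    "rt",
]


@dataclass(frozen=True)
class TrialRecord:
    """One row of a trial log.

    Attributes
    ----------
    participant_id:
        Identifier of the (real, synthetic or simulated) participant.
    task:
        ``"wcst"`` or ``"brxt"``.
    trial:
        1-based trial index within the session.
    stimulus:
        Encoded stimulus (see module docstring).
    response:
        Response location (pile 1-4 or disk 1-9); ``0`` is the
        out-of-bounds sentinel.
    correct:
        The response that would have been correct on this trial.
    feedback:
        ``+1`` (correct) or ``-1`` (incorrect).
    active_rule:
        Name of the rule the environment was enforcing on this trial.
    rt:
        Response time (ms for behavioral logs, processing cycles for
        model-generated logs).
    """

    participant_id: str
    task: str
    trial: int
    stimulus: str
    response: int
    correct: int
    feedback: int
    active_rule: str
    rt: float


def write_trial_log(trials: Iterable[TrialRecord], path: Union[str, Path]) -> None:
    """Write ``trials`` to ``path`` as CSV (header always written)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for t in trials:
            writer.writerow(
                [
                    t.participant_id,
                    t.task,
                    t.trial,
                    t.stimulus,
                    t.response,
                    t.correct,
                    t.feedback,
                    t.active_rule,
                    repr(t.rt),
                ]
            )


def read_trial_log(path: Union[str, Path]) -> List[TrialRecord]:
    """Read a trial-log CSV written by :func:`write_trial_log`.

    Malformed rows raise ``ValueError`` carrying the 1-based line number.
    """
    path = Path(path)
    records: List[TrialRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(CSV_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}")
            try:
                records.append(
                    TrialRecord(
                        participant_id=row[0],
                        task=row[1],
                        trial=int(row[2]),
                        stimulus=row[3],
                        response=int(row[4]),
                        correct=int(row[5]),
                        feedback=int(row[6]),
                        active_rule=row[7],
                        rt=float(row[8]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def records_equal(a: TrialRecord, b: TrialRecord) -> bool:
    """Field-for-field equality (exact, including the float RT)."""
    return all(getattr(a, f.name) == getattr(b, f.name) for f in fields(TrialRecord))
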