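"""Error-taxonomy scorers for the two tasks, plus feedback-conditioned RT summaries.

Card sorting (WCST)
    TE   total errors (negative-feedback trials)
    PE   perseverative errors: errors consistent with the perseverated-to
         principle (the pre-switch rule; or a rule applied unambiguously and
         consistently on more than three successive trials)
    SL3  set-loss errors: an error following three consecutive correct,
         unambiguous responses (further errors are not set losses until a
         fresh run of three is established)
    CA   categories achieved (completed runs of six correct responses)

Spatial anticipation (BRXT)
    TE      total errors, including out-of-bounds responses
    PSTIM   errors repeating the currently filled disk
    PRESP   errors repeating the participant's previous response
    PRULE   errors that would have been correct under the previously active rule

PE and SL3 are mutually exclusive (PE takes precedence); a BRXT error may be
both PRESP and PSTIM.  Out-of-bounds responses count toward TE only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .records import OUT_OF_BOUNDS, TrialRecord
from .tasks import (
    DECK_SIZE,
    RUN_LENGTH,
    TARGET_CARDS,
    TRIALS_PER_RULE,
    N_RULES,
    WCST_DIMENSIONS,
    Card,
    brxt_next_target,
    wcst_match_dims,
)


@dataclass(frozen=True)
class WcstScores:
    TE: int
    PE: int
    SL3: int
    CA: int


@dataclass(frozen=True)
class BrxtScores:
    TE: int
    PSTIM: int
    PRESP: int
    PRULE: int


def _wcst_card(record: TrialRecord) -> Card:
    return Card.decode(record.stimulus)


def wcst_trial_labels(
    trials: Sequence[TrialRecord],
    sandwich_rule: bool = True,
) -> List[Optional[str]]:
    """Per-trial error labels: ``"PE"``, ``"SL3"`` or ``None``.

    A rule applied unambiguously and consistently on more than three
    successive (error) trials becomes the perseverated-to principle for
    immediately subsequent errors.  ``sandwich_rule`` controls whether an
    ambiguous error consistent with the chained rule is neutral within such
    a chain (True) or breaks it (False).
    """
    labels: List[Optional[str]] = [None] * len(trials)
    p2p: Optional[str] = None  # perseverated-to principle
    streak_rule: Optional[str] = None
    streak_len = 0
    correct_unambig_run = 0
    prev_rule: Optional[str] = None

    for t, rec in enumerate(trials):
        if rec.active_rule not in WCST_DIMENSIONS:
            raise ValueError(f"trial {rec.trial}: missing/unknown rule annotation {rec.active_rule!r}")
        if prev_rule is not None and rec.active_rule != prev_rule:
            # sorting rule switched: the defunct rule is perseverated-to
            p2p = prev_rule
            streak_rule, streak_len = None, 0
        prev_rule = rec.active_rule

        card = _wcst_card(rec)
        valid = rec.response in TARGET_CARDS
        matches = wcst_match_dims(card, rec.response) if valid else set()
        unambiguous = len(matches) == 1
        is_error = rec.feedback < 0

        if is_error:
            is_pe = p2p is not None and valid and p2p in matches
            if is_pe:
                labels[t] = "PE"
            elif correct_unambig_run >= 3:
                labels[t] = "SL3"

        if is_error and unambiguous:
            applied = next(iter(matches))
            if applied == streak_rule:
                streak_len += 1
            else:
                streak_rule, streak_len = applied, 1
            if streak_len > 3:
                p2p = streak_rule
        elif is_error and sandwich_rule and valid and streak_rule in matches:
            pass  # ambiguous error inside an unambiguous chain: neutral
        else:
            streak_rule, streak_len = None, 0

        if not is_error and unambiguous:
            correct_unambig_run += 1
        elif is_error:
            correct_unambig_run = 0
        # a correct but ambiguous response neither extends nor breaks the run
    return labels


def score_wcst(
    trials: Sequence[TrialRecord],
    sandwich_rule: bool = True,
    require_complete: bool = False,
) -> WcstScores:
    """Score a card-sorting trial log.

    With ``require_complete=True`` the log must contain exactly one full
    64-card session.
    """
    if require_complete and len(trials) != DECK_SIZE:
        raise ValueError(f"expected a complete {DECK_SIZE}-trial session, got {len(trials)} trials")
    labels = wcst_trial_labels(trials, sandwich_rule=sandwich_rule)
    te = sum(1 for r in trials if r.feedback < 0)
    pe = sum(1 for l in labels if l == "PE")
    sl3 = sum(1 for l in labels if l == "SL3")
    ca = 0
    run = 0
    for rec in trials:
        run = run + 1 if rec.feedback > 0 else 0
        if run == RUN_LENGTH:
            ca += 1
            run = 0
    return WcstScores(TE=te, PE=pe, SL3=sl3, CA=ca)


def brxt_trial_labels(trials: Sequence[TrialRecord]) -> List[Tuple[bool, bool, bool]]:
    """Per-trial ``(is_pstim, is_presp, is_prule)`` flags (all False on correct trials)."""
    flags: List[Tuple[bool, bool, bool]] = []
    prev_rule: Optional[str] = None
    last_rule: Optional[str] = None
    prev_resp: Optional[int] = None
    for rec in trials:
        if last_rule is not None and rec.active_rule != last_rule:
            prev_rule = last_rule
        last_rule = rec.active_rule
        is_error = rec.feedback < 0
        valid = rec.response != OUT_OF_BOUNDS
        pstim = presp = prule = False
        if is_error and valid:
            stim = int(rec.stimulus)
            pstim = rec.response == stim
            presp = prev_resp is not None and prev_resp != OUT_OF_BOUNDS and rec.response == prev_resp
            prule = prev_rule is not None and rec.response == brxt_next_target(prev_rule, stim)
        flags.append((pstim, presp, prule))
        prev_resp = rec.response
    return flags


def score_brxt(trials: Sequence[TrialRecord], require_complete: bool = False) -> BrxtScores:
    """Score a spatial-anticipation trial log."""
    n_session = N_RULES * TRIALS_PER_RULE
    if require_complete and len(trials) != n_session:
        raise ValueError(f"expected a complete {n_session}-trial session, got {len(trials)} trials")
    flags = brxt_trial_labels(trials)
    te = sum(1 for r in trials if r.feedback < 0)
    pstim = sum(1 for f in flags if f[0])
    presp = sum(1 for f in flags if f[1])
    prule = sum(1 for f in flags if f[2])
    return BrxtScores(TE=te, PSTIM=pstim, PRESP=presp, PRULE=prule)


def rt_by_prior_feedback(trials: Sequence[TrialRecord]) -> Tuple[float, float]:
    """Mean RT on trials following positive vs. negative feedback.

    Trial 1 carries no prior feedback and is excluded.  An empty condition
    yields ``nan`` for that condition (flagged missing value).
    """
    after_pos: List[float] = []
    after_neg: List[float] = []
    for prev, cur in zip(trials, trials[1:]):
        (after_pos if prev.feedback > 0 else after_neg).append(cur.rt)
    mean_pos = sum(after_pos) / len(after_pos) if after_pos else math.nan
    mean_neg = sum(after_neg) / len(after_neg) if after_neg else math.nan
    return mean_pos, mean_neg


def score_table(
    sessions: Dict[str, Sequence[TrialRecord]],
    task: str,
    **kwargs,
) -> pd.DataFrame:
    """One row per participant, one column per measure (plus RT summaries)."""
    rows = []
    for pid, trials in sessions.items():
        if task == "wcst":
            scores = score_wcst(trials, **kwargs)
        elif task == "brxt":
            scores = score_brxt(trials, **kwargs)
        else:
            raise ValueError(f"unknown task {task!r}")
        rt_pos, rt_neg = rt_by_prior_feedback(trials)
        row = {"participant_id": pid, **vars(scores), "rt_after_pos": rt_pos, "rt_after_neg": rt_neg}
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")
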