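"""Synthetic participants: stochastic rule-following agents for both tasks.

The agent is intentionally *not* the dynamical loop model: it is a simple
generative policy (follow a believed rule; perseverate, lapse, or get pulled
by the stimulus / previous response with tunable probabilities), so that the
scorers and the statistics battery can be tested against data whose
structure is known by construction.

Default younger/older profiles are calibrated so that cohort-level score
means fall near the published group means, and so that RTs show the two
main effects (older slower; slower after negative feedback).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .records import OUT_OF_BOUNDS, TrialRecord, read_trial_log, write_trial_log  # noqa: F401
from .scoring import rt_by_prior_feedback, score_brxt, score_wcst
from .tasks import (
    N_POSITIONS,
    WCST_DIMENSIONS,
    SeedLike,
    as_rng,
    brxt_next_target,
    brxt_stimulus,
    build_brxt_sequence,
    make_wcst_state,
    wcst_correct_pile,
    wcst_match_dims,
    wcst_step,
)

#: rules a synthetic participant knows about on the spatial-anticipation task
KNOWN_BRXT_RULES = ("clockwise", "alternate_1_5", "counter_clockwise", "counter_clockwise_skip")


@dataclass(frozen=True)
class AgentProfile:
    """Tunable response-policy and demographics parameters for one group."""

    lapse_prob: float = 0.0       # abandon the believed rule despite positive feedback
    persev_prob: float = 0.0      # keep the believed rule despite negative feedback
    stim_pull: float = 0.0        # echo the current stimulus
    resp_pull: float = 0.0        # repeat the previous response (after an error)
    oob_prob: float = 0.0         # touch outside the response locations (BRXT only)
    explore_policy: str = "random"  # rule-candidate ordering after an error: random|cycle
    omniscient: bool = False      # always respond correctly (debug/oracle agent)
    initial_rule: Optional[str] = None
    rt_base: float = 1000.0
    rt_error_penalty: float = 250.0
    rt_noise: float = 150.0
    age_mean: float = 27.1
    age_sd: float = 9.1
    age_range: Tuple[float, float] = (19.0, 53.0)
    p_male: float = 9 / 25

    def __post_init__(self) -> None:
        for name in ("lapse_prob", "persev_prob", "stim_pull", "resp_pull", "oob_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if self.explore_policy not in ("random", "cycle"):
            raise ValueError(f"unknown explore_policy {self.explore_policy!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgentProfile":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def load_profile(path: Union[str, Path]) -> AgentProfile:
    with Path(path).open() as fh:
        return AgentProfile.from_dict(yaml.safe_load(fh))


def save_profile(profile: AgentProfile, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(profile.to_dict(), fh)


# calibrated against the published group means (coarse grid search; see tests)
DEFAULT_PROFILES: Dict[str, AgentProfile] = {
    "younger": AgentProfile(
        lapse_prob=0.018,
        persev_prob=0.18,
        stim_pull=0.008,
        resp_pull=0.12,
        explore_policy="random",
        rt_base=1050.0,
        rt_error_penalty=260.0,
        rt_noise=160.0,
        age_mean=27.1,
        age_sd=9.1,
        age_range=(19.0, 53.0),
        p_male=9 / 25,
    ),
    "older": AgentProfile(
        lapse_prob=0.060,
        persev_prob=0.08,
        stim_pull=0.003,
        resp_pull=0.15,
        explore_policy="random",
        rt_base=1600.0,
        rt_error_penalty=430.0,
        rt_noise=220.0,
        age_mean=70.8,
        age_sd=6.4,
        age_range=(62.0, 84.0),
        p_male=8 / 25,
    ),
}


def _rt(profile: AgentProfile, prev_feedback: int, rng: np.random.Generator) -> float:
    rt = profile.rt_base
    if prev_feedback < 0:
        rt += profile.rt_error_penalty
    rt += rng.normal(0.0, profile.rt_noise)
    return float(max(rt, 50.0))


def _gen_wcst_session(
    profile: AgentProfile,
    rng: np.random.Generator,
    participant_id: str,
) -> List[TrialRecord]:
    state = make_wcst_state(seed=rng)
    believed = profile.initial_rule or (
        state.active_rule if profile.omniscient else str(rng.choice(WCST_DIMENSIONS))
    )
    trials: List[TrialRecord] = []
    prev_feedback = 0
    prev_resp: Optional[int] = None
    trial_no = 0
    while not state.done:
        trial_no += 1
        card = state.current_card
        rule_now = state.active_rule
        if profile.omniscient:
            resp = wcst_correct_pile(card, rule_now)
        elif (prev_resp is not None and prev_feedback < 0
              and rng.random() < profile.resp_pull):
            resp = prev_resp
        elif rng.random() < profile.stim_pull:
            # stimulus-driven capture: the pile sharing most features with the card
            resp = max(range(1, 5), key=lambda p: len(wcst_match_dims(card, p)))
        else:
            resp = wcst_correct_pile(card, believed)
        feedback, state = wcst_step(state, resp)
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                task="wcst",
                trial=trial_no,
                stimulus=card.encode(),
                response=resp,
                correct=wcst_correct_pile(card, rule_now),
                feedback=feedback,
                active_rule=rule_now,
                rt=_rt(profile, prev_feedback, rng),
            )
        )
        if not profile.omniscient:
            others = [d for d in WCST_DIMENSIONS if d != believed]
            if feedback > 0:
                if rng.random() < profile.lapse_prob:
                    believed = str(rng.choice(others))
            elif rng.random() >= profile.persev_prob:
                if profile.explore_policy == "cycle":
                    believed = others[0]
                else:
                    believed = str(rng.choice(others))
        prev_feedback = feedback
        prev_resp = resp
    return trials


def _gen_brxt_session(
    profile: AgentProfile,
    rng: np.random.Generator,
    participant_id: str,
) -> List[TrialRecord]:
    spec = build_brxt_sequence(seed=rng)
    believed: Optional[str] = profile.initial_rule
    prior_believed: Optional[str] = None
    trials: List[TrialRecord] = []
    prev_feedback = 0
    prev_resp: Optional[int] = None
    for t in range(1, len(spec.target_sequence) + 1):
        stim = brxt_stimulus(spec, t)
        target = spec.target_sequence[t - 1]
        if profile.omniscient:
            resp = target
        elif rng.random() < profile.oob_prob:
            resp = OUT_OF_BOUNDS
        elif rng.random() < profile.stim_pull:
            resp = stim
        elif (prev_resp not in (None, OUT_OF_BOUNDS) and prev_feedback < 0
              and rng.random() < profile.resp_pull):
            resp = prev_resp
        elif believed is not None:
            resp = brxt_next_target(believed, stim)
        else:
            resp = int(rng.integers(1, N_POSITIONS + 1))
        feedback = 1 if resp == target else -1
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                task="brxt",
                trial=t,
                stimulus=str(stim),
                response=resp,
                correct=target,
                feedback=feedback,
                active_rule=spec.active_rule(t),
                rt=_rt(profile, prev_feedback, rng),
            )
        )
        if not profile.omniscient:
            # the revealed target is next trial's stimulus: infer consistent rules
            consistent = [r for r in KNOWN_BRXT_RULES if brxt_next_target(r, stim) == target]
            if feedback > 0:
                if believed is None and consistent:
                    believed = consistent[0]
                elif rng.random() < profile.lapse_prob:
                    # novelty-seeking lapse: avoid drifting back to the rule
                    # just abandoned (which would read as rule perseveration)
                    pool = [r for r in KNOWN_BRXT_RULES if r not in (believed, prior_believed)]
                    prior_believed = believed
                    believed = str(rng.choice(pool))
            elif rng.random() >= profile.persev_prob:
                prior_believed = believed
                if consistent:
                    believed = str(rng.choice(consistent))
                elif profile.explore_policy == "cycle" and believed is not None:
                    known = list(KNOWN_BRXT_RULES)
                    believed = known[(known.index(believed) + 1) % len(known)]
                else:
                    believed = str(rng.choice(KNOWN_BRXT_RULES))
        prev_feedback = feedback
        prev_resp = resp
    return trials


def gen_agent_session(
    task: str,
    profile: AgentProfile,
    seed: SeedLike,
    participant_id: str = "agent",
) -> List[TrialRecord]:
    """Play one full session of ``task`` with the stochastic policy of ``profile``."""
    rng = as_rng(seed)
    if task == "wcst":
        return _gen_wcst_session(profile, rng, participant_id)
    if task == "brxt":
        return _gen_brxt_session(profile, rng, participant_id)
    raise ValueError(f"unknown task {task!r}")


def gen_cohort(
    young_profile: Optional[AgentProfile] = None,
    old_profile: Optional[AgentProfile] = None,
    n_per_group: int = 25,
    seed: SeedLike = None,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], List[TrialRecord]]]:
    """Simulate both tasks for a two-group cohort.

    Returns a cohort table (one row per participant) and the bundle of trial
    logs keyed by ``(participant_id, task)``.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    young_profile = young_profile or DEFAULT_PROFILES["younger"]
    old_profile = old_profile or DEFAULT_PROFILES["older"]
    rng = as_rng(seed)
    rows = []
    logs: Dict[Tuple[str, str], List[TrialRecord]] = {}
    for group, profile in [("younger", young_profile), ("older", old_profile)]:
        for k in range(n_per_group):
            pid = f"{group}_{k + 1:03d}"
            age = float(np.clip(rng.normal(profile.age_mean, profile.age_sd), *profile.age_range))
            gender = "m" if rng.random() < profile.p_male else "f"
            wcst = gen_agent_session("wcst", profile, rng, pid)
            brxt = gen_agent_session("brxt", profile, rng, pid)
            logs[(pid, "wcst")] = wcst
            logs[(pid, "brxt")] = brxt
            ws = score_wcst(wcst)
            bs = score_brxt(brxt)
            w_pos, w_neg_rt = rt_by_prior_feedback(wcst)
            b_pos, b_neg_rt = rt_by_prior_feedback(brxt)
            rt_pos = float(np.nanmean([w_pos, b_pos]))
            rt_neg = float(np.nanmean([w_neg_rt, b_neg_rt]))
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "age": age,
                    "gender": gender,
                    "wcst_TE": ws.TE,
                    "wcst_PE": ws.PE,
                    "wcst_SL3": ws.SL3,
                    "wcst_CA": ws.CA,
                    "brxt_TE": bs.TE,
                    "brxt_PSTIM": bs.PSTIM,
                    "brxt_PRESP": bs.PRESP,
                    "brxt_PRULE": bs.PRULE,
                    "rt_after_pos": rt_pos,
                    "rt_after_neg": rt_neg,
                }
            )
    return pd.DataFrame(rows), logs
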