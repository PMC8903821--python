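import numpy as np
import pytest

from schemabg.records import TrialRecord
from schemabg.tasks import make_wcst_state, wcst_correct_pile, wcst_step, TARGET_CARDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def play_wcst(responder, seed=0, participant_id="p"):
    """Drive a full 64-card session with ``responder(state) -> pile``."""
    state = make_wcst_state(seed=seed)
    trials = []
    t = 0
    while not state.done:
        t += 1
        card = state.current_card
        rule = state.active_rule
        resp = responder(state)
        feedback, state = wcst_step(state, resp)
        trials.append(
            TrialRecord(participant_id, "wcst", t, card.encode(), resp,
                        wcst_correct_pile(card, rule), feedback, rule, 500.0)
        )
    return trials


def always_wrong_pile(state):
    """A pile mismatching the card on the active rule's dimension."""
    card = state.current_card
    rule = state.active_rule
    for pile, target in TARGET_CARDS.items():
        if card.feature(rule) != target.feature(rule):
            return pile
    raise AssertionError("unreachable: only one pile matches per dimension")


def omniscient_pile(state):
    return wcst_correct_pile(state.current_card, state.active_rule)
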