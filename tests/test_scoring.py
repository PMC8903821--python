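import math

import numpy as np
import pytest

from schemabg.records import OUT_OF_BOUNDS, TrialRecord
from schemabg.scoring import (
    brxt_trial_labels,
    rt_by_prior_feedback,
    score_brxt,
    score_table,
    score_wcst,
    wcst_trial_labels,
)
from schemabg.synth import AgentProfile, gen_agent_session
from schemabg.tasks import Card, build_brxt_sequence, brxt_stimulus
from conftest import always_wrong_pile, omniscient_pile, play_wcst


def wrec(trial, card, resp, feedback, rule, rt=500.0):
    return TrialRecord("p", "wcst", trial, Card(*card).encode(), resp,
                       0, feedback, rule, rt)


def brec(trial, stim, resp, correct, rule, rt=500.0):
    fb = 1 if resp == correct else -1
    return TrialRecord("p", "brxt", trial, str(stim), resp, correct, fb, rule, rt)


class TestWcstExtremes:
    def test_always_wrong_te_64(self):
        trials = play_wcst(always_wrong_pile, seed=0)
        assert score_wcst(trials, require_complete=True).TE == 64

    def test_perfect_responder(self):
        trials = play_wcst(omniscient_pile, seed=1)
        scores = score_wcst(trials, require_complete=True)
        assert (scores.TE, scores.PE, scores.SL3, scores.CA) == (0, 0, 0, 10)


class TestSetLoss:
    def test_sl3_after_three_correct_unambiguous(self):
        # rule stays 'color'; three correct unambiguous sorts, then an error
        # matching no prior rule: a set-loss, not a perseveration
        trials = [
            wrec(1, (2, "red", "circle"), 1, 1, "color"),   # matches pile 1 on color only
            wrec(2, (3, "green", "circle"), 2, 1, "color"),
            wrec(3, (4, "yellow", "star"), 3, 1, "color"),
            wrec(4, (2, "red", "circle"), 3, -1, "color"),  # matches pile 3 on nothing
        ]
        scores = score_wcst(trials)
        assert scores.SL3 == 1
        assert scores.PE == 0

    def test_errors_after_set_loss_not_counted(self):
        trials = [
            wrec(1, (2, "red", "circle"), 1, 1, "color"),
            wrec(2, (3, "green", "circle"), 2, 1, "color"),
            wrec(3, (4, "yellow", "star"), 3, 1, "color"),
            wrec(4, (2, "red", "circle"), 3, -1, "color"),
            wrec(5, (2, "red", "circle"), 3, -1, "color"),  # immediately after: not SL3
        ]
        assert score_wcst(trials).SL3 == 1

    def test_no_sl3_after_only_two_correct(self):
        trials = [
            wrec(1, (2, "red", "circle"), 1, 1, "color"),
            wrec(2, (3, "green", "circle"), 2, 1, "color"),
            wrec(3, (2, "red", "circle"), 3, -1, "color"),
        ]
        assert score_wcst(trials).SL3 == 0


class TestPerseveration:
    def test_pe_after_rule_change(self):
        # rule changes color -> shape; continuing to sort by color is a PE
        trials = [
            wrec(1, (2, "red", "circle"), 1, 1, "color"),
            wrec(2, (3, "red", "star"), 1, -1, "shape"),  # sorts by color after the switch
        ]
        scores = score_wcst(trials)
        assert scores.PE == 1
        assert scores.SL3 == 0

    def test_pe_and_sl3_mutually_exclusive_per_trial(self):
        profile = AgentProfile(lapse_prob=0.1, persev_prob=0.6, stim_pull=0.05, resp_pull=0.1)
        for seed in range(5):
            trials = gen_agent_session("wcst", profile, seed=seed)
            labels = wcst_trial_labels(trials)
            assert all(l in (None, "PE", "SL3") for l in labels)
            scores = score_wcst(trials)
            assert scores.PE + scores.SL3 <= scores.TE

    def test_unambiguous_chain_establishes_principle(self):
        # >3 successive unambiguous applications of 'number' (all errors under
        # 'color') make 'number' the perseverated-to principle
        chain = [
            wrec(t, (1, "green", "star"), 1, -1, "color") for t in range(1, 5)
        ]  # card matches pile 1 on number only; correct pile under color is 2
        probe = [wrec(5, (2, "red", "circle"), 2, -1, "color")]  # matches pile 2 on number only
        scores = score_wcst(chain + probe)
        assert wcst_trial_labels(chain + probe)[4] == "PE"


class TestWcstInvariants:
    def test_monotonicity_te(self):
        trials = play_wcst(omniscient_pile, seed=2)[:10]
        base = score_wcst(trials).TE
        extended = trials + [wrec(11, (2, "red", "circle"), 3, -1, "color")]
        assert score_wcst(extended).TE == base + 1

    def test_purity(self):
        trials = gen_agent_session("wcst", AgentProfile(persev_prob=0.5, lapse_prob=0.05), seed=3)
        assert score_wcst(trials) == score_wcst(trials)

    def test_noise_free_agent_scores_zero(self):
        profile = AgentProfile(omniscient=True)
        for task in ("wcst", "brxt"):
            trials = gen_agent_session(task, profile, seed=0)
            scorer = score_wcst if task == "wcst" else score_brxt
            assert scorer(trials).TE == 0

    def test_incomplete_session_rejected_when_required(self):
        trials = play_wcst(omniscient_pile, seed=0)[:10]
        with pytest.raises(ValueError):
            score_wcst(trials, require_complete=True)

    def test_missing_rule_annotation_rejected(self):
        bad = [TrialRecord("p", "wcst", 1, "1:red:triangle", 1, 1, 1, "", 100.0)]
        with pytest.raises(ValueError):
            score_wcst(bad)


class TestBrxtScoring:
    def test_always_wrong_te_50(self):
        spec = build_brxt_sequence(seed=0)
        trials = []
        for t in range(1, 51):
            target = spec.target_sequence[t - 1]
            resp = target % 9 + 1  # always a different disk
            trials.append(brec(t, brxt_stimulus(spec, t), resp, target, spec.active_rule(t)))
        assert score_brxt(trials, require_complete=True).TE == 50

    def test_stimulus_perseverator(self):
        spec = build_brxt_sequence(seed=1)
        trials = [
            brec(t, brxt_stimulus(spec, t), brxt_stimulus(spec, t),
                 spec.target_sequence[t - 1], spec.active_rule(t))
            for t in range(1, 51)
        ]
        scores = score_brxt(trials)
        # every error with response == current stimulus increments PSTIM
        expected = sum(1 for t in trials if t.feedback < 0)
        assert scores.PSTIM == expected
        assert scores.TE == expected

    def test_prule_on_first_trial_after_change(self):
        trials = [
            brec(10, 4, 5, 5, "clockwise"),     # correct under clockwise
            brec(11, 5, 6, 4, "counter_clockwise"),  # follows the defunct rule
        ]
        assert score_brxt(trials).PRULE == 1

    def test_prule_undefined_before_first_change(self):
        trials = [brec(1, 4, 3, 5, "clockwise"), brec(2, 5, 3, 6, "clockwise")]
        assert score_brxt(trials).PRULE == 0

    def test_presp_and_pstim_can_coincide(self):
        trials = [
            brec(11, 4, 7, 5, "clockwise"),
            brec(12, 7, 7, 6, "clockwise"),  # repeats own response == current stimulus
        ]
        flags = brxt_trial_labels(trials)
        assert flags[1][0] and flags[1][1]  # PSTIM and PRESP

    def test_out_of_bounds_counts_te_only(self):
        trials = [
            brec(11, 4, 5, 5, "clockwise"),
            TrialRecord("p", "brxt", 12, "5", OUT_OF_BOUNDS, 6, -1, "clockwise", 100.0),
        ]
        scores = score_brxt(trials)
        assert scores.TE == 1
        assert scores.PSTIM == scores.PRESP == scores.PRULE == 0


class TestRtByPriorFeedback:
    def test_constant_rt(self):
        trials = [brec(t, 1, 2, 2 if t % 2 else 3, "clockwise", rt=250.0) for t in range(1, 7)]
        assert rt_by_prior_feedback(trials) == (250.0, 250.0)

    def test_stratified_means(self):
        trials = [
            brec(1, 1, 2, 2, "clockwise", rt=999.0),   # prior for t2: positive
            brec(2, 2, 3, 3, "clockwise", rt=100.0),
            brec(3, 3, 5, 4, "clockwise", rt=100.0),   # error -> next after negative
            brec(4, 4, 5, 5, "clockwise", rt=120.0),
        ]
        assert rt_by_prior_feedback(trials) == (100.0, 120.0)

    def test_matches_brute_force_partition(self, rng):
        trials = gen_agent_session(
            "brxt", AgentProfile(persev_prob=0.3, lapse_prob=0.1, rt_noise=200.0), seed=9)
        after_pos = [b.rt for a, b in zip(trials, trials[1:]) if a.feedback > 0]
        after_neg = [b.rt for a, b in zip(trials, trials[1:]) if a.feedback < 0]
        got = rt_by_prior_feedback(trials)
        assert got[0] == pytest.approx(np.mean(after_pos))
        assert got[1] == pytest.approx(np.mean(after_neg))

    def test_empty_condition_flagged_nan(self):
        trials = [brec(t, 1, 2, 2, "clockwise") for t in range(1, 4)]  # all correct
        pos, neg = rt_by_prior_feedback(trials)
        assert not math.isnan(pos)
        assert math.isnan(neg)


def test_score_table_shape():
    sessions = {
        f"p{k}": gen_agent_session("wcst", AgentProfile(persev_prob=0.4), seed=k)
        for k in range(3)
    }
    table = score_table(sessions, "wcst")
    assert list(table.index) == ["p0", "p1", "p2"]
    assert {"TE", "PE", "SL3", "CA", "rt_after_pos", "rt_after_neg"} <= set(table.columns)
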