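"""Schema-selection model: competing cortico-basal-ganglia-thalamic loops.

Each schema (cognitive = task rule, sensorimotor = concrete response) owns a
loop of logistic units -- CTX, striatum D1/D2, STN, GPe, GPi, THAL -- wired
for selective disinhibition: CTX excites D1/D2/STN; D1 inhibits GPi; D2
inhibits GPe; GPe inhibits STN and GPi; STN excites the GPi of *every*
schema in its set; GPi inhibits THAL; THAL excites CTX.  Schemas within a
set compete; cognitive schemas cooperate with sensorimotor schemas by
routing top-down excitation toward the response they imply for the current
stimulus.

Learning has two sites:

* sensorimotor gain adaptation, driven by conflict between response units
  (the product-of-outputs update of the CTX gain ``alpha_sma``), applied
  once per feedback event;
* striatal threshold learning in the cognitive loops: a reward prediction
  error (actual schema feedback minus the schema's median activation on the
  last trial, signed by the environment feedback) moves ``beta_str`` with
  rate ``eps_str``, clipped to [0, 1].

The four free parameters are ``w_neg`` (mismatch reward sensitivity),
``m_r`` (memory for negative feedback), ``eps_str`` and ``eps_sma``.  The
fixed dynamics constants below are not empirically constrained; absolute
cycle counts are therefore implementation-relative and only orderings and
fitted-error statistics are meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import TrialRecord
from .scoring import rt_by_prior_feedback, score_brxt, score_wcst
from .tasks import (
    DISTRACTOR_RULES,
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

logger = logging.getLogger(__name__)

# state-matrix row layout
CTX, D1, D2, STN, GPE, GPI, THAL = range(7)
N_UNITS = 7

#: cognitive rule inventory per task
WCST_COG_RULES = WCST_DIMENSIONS  # 3 cognitive schemas, 4 response piles
BRXT_KNOWN_RULES = ("clockwise", "alternate_1_5", "counter_clockwise", "counter_clockwise_skip")


def logistic(x, alpha: float, beta: float):
    """Standard logistic saturation ``1 / (1 + exp(-alpha * (x - beta)))`` (overflow-safe)."""
    z = np.clip(np.multiply(alpha, np.subtract(x, beta)), -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class Dynamics:
    """Fixed dynamics constants (inter-nucleus weights, gains, selection rule).

    Defaults were chosen so that the selection invariants hold (sustained
    asymmetric input yields exactly one super-threshold schema; raised
    striatal thresholds demote the dominant schema).  All values are
    configuration, not reproduction targets.
    """

    alpha_bg: float = 8.0          # gain of basal-ganglia / thalamic units
    alpha_cog: float = 8.0         # fixed CTX gain of cognitive schemas
    tau: float = 0.25              # leaky-integration blend rate
    # inter-nucleus weights
    w_cs: float = 1.0              # CTX -> striatum
    lam_da: float = 0.2            # tonic D1/D2 asymmetry (D1 gets 1+lam, D2 gets 1-lam)
    w_cstn: float = 0.5            # CTX -> STN
    w_gstn: float = 0.6            # GPe -| STN
    w_d2: float = 0.7              # D2 -| GPe
    w_d1: float = 1.2              # D1 -| GPi
    w_ge: float = 0.4              # GPe -| GPi
    w_stn: float = 0.35            # STN -> GPi (diffuse, all schemas in set)
    w_gt: float = 0.8              # GPi -| THAL
    thal_drive: float = 0.5        # tonic thalamic drive
    w_tc: float = 0.6              # THAL -> CTX
    # unit thresholds
    beta_ctx_cog: float = 0.80
    beta_ctx_sma: float = 0.65
    beta_stn: float = 0.10
    beta_gpe: float = -0.20
    beta_gpi: float = -0.55
    beta_thal: float = 0.10
    beta_str_sma: float = 0.45     # fixed striatal threshold of sensorimotor loops
    beta_str_init: float = 0.50    # initial striatal threshold of cognitive loops
    rest: float = 0.10             # resting activation of every unit
    # selection rule
    theta_sel: float = 0.85
    k_sel: int = 3
    cycle_cap: int = 250
    carryover: float = 0.37        # fraction of trial-end state retained across trials
    # external input routing
    cog_input: float = 0.55        # constant drive to every cognitive schema
    cog_noise_half: float = 0.05   # per-trial uniform noise on cognitive drive
    cog_bonus: float = 0.22        # bottom-up drive to rules consistent with the
                                   # observed transition of filled positions (BRXT)
    sma_noise_half: float = 0.10   # per-cycle uniform noise on sensorimotor drive
    sma_bias_half: float = 0.27    # per-trial uniform bias on sensorimotor drive
    w_td: float = 0.70             # top-down weight (cognitive CTX -> implied response)
    w_bu: float = 0.50             # WCST bottom-up weight per matching feature (of 3)
    w_prime: float = 0.13          # response priming: bottom-up bonus on the
                                   # previously selected response location
    brxt_stim_in: float = -0.08    # bottom-up drive of the currently filled disk
                                   # (mildly suppressed: the disk is known to move)
    # gain-adaptation noise (scales the conflict product): U(center-half, center+half)
    zeta_sma_center: float = 3.0
    zeta_sma_half: float = 0.25
    zeta_str_half: float = 0.05    # striatal update noise half-width
    literal_gain_rule: bool = False  # use the literal (1 + eps + o) product reading


@dataclass(frozen=True)
class ModelParams:
    """The four free parameters plus the fixed dynamics constants."""

    w_neg: float = 0.2
    m_r: float = 0.0
    eps_str: float = 0.3
    eps_sma: float = 0.5
    dynamics: Dynamics = field(default_factory=Dynamics)

    def __post_init__(self) -> None:
        for name in ("w_neg", "m_r", "eps_str", "eps_sma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dynamics.cycle_cap <= 0:
            raise ValueError("cycle_cap must be positive")

    def free_vector(self) -> np.ndarray:
        return np.array([self.w_neg, self.m_r, self.eps_str, self.eps_sma])

    def with_free(self, vec: Sequence[float]) -> "ModelParams":
        w, m, es, ea = (float(v) for v in vec)
        return replace(self, w_neg=w, m_r=m, eps_str=es, eps_sma=ea)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        dyn = d.pop("dynamics", None)
        if dyn is not None:
            d["dynamics"] = Dynamics(**dyn)
        return cls(**d)


# ---------------------------------------------------------------------------
# Elementary learning operations
# ---------------------------------------------------------------------------

def schema_feedback(matching: bool, w_neg: float, m_r: float, f_prev: float, r_prev: float) -> float:
    """Schema-level feedback: +1 for matching schemas, a ``w_neg``/``m_r``
    modulated baseline for mismatching ones."""
    if matching:
        return 1.0
    return 2.0 * w_neg - 1.0 - m_r * f_prev * r_prev


def prediction_error(r: float, f_i: float, a_i: float) -> float:
    """Reward prediction error: signed actual reward ``r * f_i`` minus the
    anticipated level ``a_i`` (the schema's median activation last trial)."""
    return r * f_i - a_i


def update_striatum(beta: float, delta: float, eps_str: float, zeta: float = 0.0) -> float:
    """One striatal threshold step, clipped to [0, 1]."""
    return float(min(1.0, max(0.0, beta - eps_str * delta * (1.0 + zeta))))


def update_gain(
    sma_outputs: Sequence[float],
    eps_sma: float,
    zeta_sma: float,
    literal: bool = False,
) -> float:
    """Conflict-adaptive sensorimotor gain.

    Adopted reading: ``alpha = 1 + zeta * prod(1 + eps * o_i)`` so that
    ``eps_sma = 0`` disables conflict-driven gain change.  ``literal=True``
    uses the printed ``prod(1 + eps + o_i)`` form instead.
    """
    prod = 1.0
    for o in sma_outputs:
        prod *= (1.0 + eps_sma + o) if literal else (1.0 + eps_sma * o)
    return 1.0 + zeta_sma * prod


# ---------------------------------------------------------------------------
# Cycle kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _cycle_kernel(
    S_c, S_s, beta_c, beta_s,
    alpha_cog, alpha_sma, alpha_bg,
    I_c, bu_s, R, noise_s,
    w_cs1, w_cs2, w_cstn, w_gstn, w_d2, w_d1, w_ge, w_stn, w_gt,
    thal_drive, w_tc,
    b_ctx_c, b_ctx_s, b_stn, b_gpe, b_gpi, b_thal,
    w_td, tau, theta, k_sel, cap,
    ctx_hist_c, sustain,
):
    """Run up to ``cap`` synchronous cycles of both loop sets.

    Returns ``(winner, cycles)``; ``winner`` is -1 if the cap was exhausted.
    Cognitive CTX activations per cycle are written into ``ctx_hist_c``.
    """
    n_c = S_c.shape[1]
    n_s = S_s.shape[1]
    new_c = np.empty((N_UNITS, n_c))
    new_s = np.empty((N_UNITS, n_s))
    winner = -1
    cycles = 0
    for t in range(cap):
        # --- cognitive set ---
        stn_sum = 0.0
        for j in range(n_c):
            stn_sum += S_c[STN, j]
        for j in range(n_c):
            ctx = S_c[CTX, j]
            z = alpha_cog * (I_c[j] + w_tc * S_c[THAL, j] - b_ctx_c)
            new_c[CTX, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cs1 * ctx - beta_c[j])
            new_c[D1, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cs2 * ctx - beta_c[j])
            new_c[D2, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cstn * ctx - w_gstn * S_c[GPE, j] - b_stn)
            new_c[STN, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (-w_d2 * S_c[D2, j] - b_gpe)
            new_c[GPE, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_stn * stn_sum - w_d1 * S_c[D1, j] - w_ge * S_c[GPE, j] - b_gpi)
            new_c[GPI, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (thal_drive - w_gt * S_c[GPI, j] - b_thal)
            new_c[THAL, j] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
        # --- sensorimotor set (top-down input from current cognitive CTX) ---
        stn_sum_s = 0.0
        for p in range(n_s):
            stn_sum_s += S_s[STN, p]
        for p in range(n_s):
            td = 0.0
            for j in range(n_c):
                td += R[j, p] * S_c[CTX, j]
            inp = bu_s[p] + w_td * td + noise_s[t, p]
            ctx = S_s[CTX, p]
            z = alpha_sma * (inp + w_tc * S_s[THAL, p] - b_ctx_s)
            new_s[CTX, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cs1 * ctx - beta_s[p])
            new_s[D1, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cs2 * ctx - beta_s[p])
            new_s[D2, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_cstn * ctx - w_gstn * S_s[GPE, p] - b_stn)
            new_s[STN, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (-w_d2 * S_s[D2, p] - b_gpe)
            new_s[GPE, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (w_stn * stn_sum_s - w_d1 * S_s[D1, p] - w_ge * S_s[GPE, p] - b_gpi)
            new_s[GPI, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
            z = alpha_bg * (thal_drive - w_gt * S_s[GPI, p] - b_thal)
            new_s[THAL, p] = 1.0 / (1.0 + math.exp(-max(min(z, 60.0), -60.0)))
        # --- leaky blend ---
        for u in range(N_UNITS):
            for j in range(n_c):
                S_c[u, j] += tau * (new_c[u, j] - S_c[u, j])
            for p in range(n_s):
                S_s[u, p] += tau * (new_s[u, p] - S_s[u, p])
        for j in range(n_c):
            ctx_hist_c[t, j] = S_c[CTX, j]
        cycles = t + 1
        # --- sustained-selection check ---
        found = -1
        best = -1.0
        for p in range(n_s):
            if S_s[CTX, p] > theta:
                sustain[p] += 1
                if sustain[p] >= k_sel and S_s[CTX, p] > best:
                    found = p
                    best = S_s[CTX, p]
            else:
                sustain[p] = 0
        if found >= 0:
            winner = found
            break
    return winner, cycles


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cycle_kernel = njit(cache=True, fastmath=False)(_cycle_kernel)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# State containers and spec-level operations
# ---------------------------------------------------------------------------

@dataclass
class SchemaLoopState:
    """Mutable joint state of the cognitive and sensorimotor loop sets."""

    cog: np.ndarray                 # (7, n_cog) unit activations
    sma: np.ndarray                 # (7, n_sma)
    beta_str_cog: np.ndarray        # learned striatal thresholds, cognitive loops
    beta_str_sma: np.ndarray        # fixed striatal thresholds, sensorimotor loops
    alpha_sma: float                # adaptive sensorimotor CTX gain
    f_prev: np.ndarray              # previous schema feedback f_i(t-1)
    r_prev: float                   # previous environment reward r(t-1)
    a_last: np.ndarray              # median cognitive CTX activation, last trial

    @property
    def n_cog(self) -> int:
        return self.cog.shape[1]

    @property
    def n_sma(self) -> int:
        return self.sma.shape[1]


def init_state(n_cog: int, n_sma: int, params: ModelParams) -> SchemaLoopState:
    dyn = params.dynamics
    return SchemaLoopState(
        cog=np.full((N_UNITS, n_cog), dyn.rest),
        sma=np.full((N_UNITS, n_sma), dyn.rest),
        beta_str_cog=np.full(n_cog, dyn.beta_str_init),
        beta_str_sma=np.full(n_sma, dyn.beta_str_sma),
        alpha_sma=1.0 + dyn.zeta_sma_center,
        f_prev=np.zeros(n_cog),
        r_prev=1.0,
        a_last=np.full(n_cog, dyn.rest),
    )


@dataclass(frozen=True)
class TrialInputs:
    """External input routing for one trial."""

    cog_drive: np.ndarray           # (n_cog,) external input to cognitive CTX
    sma_drive: np.ndarray           # (n_sma,) bottom-up input to sensorimotor CTX
    routing: np.ndarray             # (n_cog, n_sma) 0/1: rule j implies response p


def _kernel_args(state: SchemaLoopState, inputs: TrialInputs, params: ModelParams, noise_s):
    dyn = params.dynamics
    return (
        state.cog, state.sma, state.beta_str_cog, state.beta_str_sma,
        dyn.alpha_cog, state.alpha_sma, dyn.alpha_bg,
        inputs.cog_drive, inputs.sma_drive, inputs.routing, noise_s,
        dyn.w_cs * (1.0 + dyn.lam_da), dyn.w_cs * (1.0 - dyn.lam_da),
        dyn.w_cstn, dyn.w_gstn, dyn.w_d2, dyn.w_d1, dyn.w_ge, dyn.w_stn, dyn.w_gt,
        dyn.thal_drive, dyn.w_tc,
        dyn.beta_ctx_cog, dyn.beta_ctx_sma, dyn.beta_stn, dyn.beta_gpe, dyn.beta_gpi, dyn.beta_thal,
        dyn.w_td, dyn.tau, dyn.theta_sel,
    )


def step_loops(state: SchemaLoopState, inputs: TrialInputs, params: ModelParams) -> SchemaLoopState:
    """One synchronous integration cycle (in place; returns ``state``)."""
    noise = np.zeros((1, state.n_sma))
    hist = np.empty((1, state.n_cog))
    sustain = np.zeros(state.n_sma, dtype=np.int64)
    _cycle_kernel(*_kernel_args(state, inputs, params, noise),
                  np.int64(10**9), np.int64(1), hist, sustain)
    return state


def select_and_respond(
    state: SchemaLoopState,
    inputs: TrialInputs,
    params: ModelParams,
    rng: np.random.Generator,
) -> Tuple[int, int, bool]:
    """Iterate cycles until one sensorimotor schema is sustained above threshold.

    Returns ``(response_index, cycles, capped)``; on cap exhaustion the most
    active schema wins (ties broken uniformly at random).  Also refreshes
    ``state.a_last`` with the median cognitive CTX activation of the trial.
    """
    dyn = params.dynamics
    cap = dyn.cycle_cap
    noise = rng.uniform(-dyn.sma_noise_half, dyn.sma_noise_half, size=(cap, state.n_sma))
    hist = np.empty((cap, state.n_cog))
    sustain = np.zeros(state.n_sma, dtype=np.int64)
    winner, cycles = _cycle_kernel(
        *_kernel_args(state, inputs, params, noise),
        np.int64(dyn.k_sel), np.int64(cap), hist, sustain,
    )
    capped = winner < 0
    if capped:
        acts = state.sma[CTX]
        top = np.flatnonzero(acts == acts.max())
        winner = int(top[rng.integers(len(top))]) if len(top) > 1 else int(top[0])
        logger.debug("cycle cap exhausted; falling back to argmax schema %d", winner)
    state.a_last = np.median(hist[:cycles], axis=0)
    return int(winner), int(cycles), capped


def _apply_feedback(
    state: SchemaLoopState,
    matching: np.ndarray,
    r: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> None:
    """Per-feedback learning: schema feedback -> prediction error -> striatal
    thresholds, then the sensorimotor gain update."""
    dyn = params.dynamics
    f = np.empty(state.n_cog)
    for i in range(state.n_cog):
        f[i] = schema_feedback(bool(matching[i]), params.w_neg, params.m_r,
                               float(state.f_prev[i]), state.r_prev)
        delta = prediction_error(r, f[i], float(state.a_last[i]))
        zeta = rng.uniform(-dyn.zeta_str_half, dyn.zeta_str_half)
        state.beta_str_cog[i] = update_striatum(
            float(state.beta_str_cog[i]), delta, params.eps_str, zeta)
    zeta_sma = rng.uniform(dyn.zeta_sma_center - dyn.zeta_sma_half,
                           dyn.zeta_sma_center + dyn.zeta_sma_half)
    state.alpha_sma = update_gain(state.sma[CTX], params.eps_sma, zeta_sma,
                                  literal=dyn.literal_gain_rule)
    state.f_prev = f
    state.r_prev = r


def _relax(state: SchemaLoopState, dyn: Dynamics) -> None:
    """Between-trial decay toward rest, keeping a configurable carryover."""
    for S in (state.cog, state.sma):
        S *= dyn.carryover
        S += (1.0 - dyn.carryover) * dyn.rest


def _cog_drive(state: SchemaLoopState, dyn: Dynamics, rng: np.random.Generator) -> np.ndarray:
    return dyn.cog_input + rng.uniform(-dyn.cog_noise_half, dyn.cog_noise_half, state.n_cog)


# ---------------------------------------------------------------------------
# Session runners
# ---------------------------------------------------------------------------

def _run_wcst_session(params: ModelParams, rng: np.random.Generator, pid: str) -> List[TrialRecord]:
    dyn = params.dynamics
    n_cog, n_sma = len(WCST_COG_RULES), 4
    state = init_state(n_cog, n_sma, params)
    env = make_wcst_state(seed=rng)
    trials: List[TrialRecord] = []
    trial_no = 0
    prev_resp = 0
    while not env.done:
        trial_no += 1
        card = env.current_card
        rule_now = env.active_rule
        routing = np.zeros((n_cog, n_sma))
        for j, dim in enumerate(WCST_COG_RULES):
            routing[j, wcst_correct_pile(card, dim) - 1] = 1.0
        bu = np.array([dyn.w_bu * len(wcst_match_dims(card, p)) / 3.0 for p in range(1, 5)])
        bu += rng.uniform(-dyn.sma_bias_half, dyn.sma_bias_half, n_sma)
        if prev_resp:
            bu[prev_resp - 1] += dyn.w_prime
        inputs = TrialInputs(_cog_drive(state, dyn, rng), bu, routing)
        widx, cycles, _ = select_and_respond(state, inputs, params, rng)
        response = widx + 1
        feedback, env = wcst_step(env, response)
        # a cognitive schema matches iff the card matches the chosen pile on its dimension
        resp_matches = wcst_match_dims(card, response)
        matching = np.array([dim in resp_matches for dim in WCST_COG_RULES])
        trials.append(
            TrialRecord(pid, "wcst", trial_no, card.encode(), response,
                        wcst_correct_pile(card, rule_now), feedback, rule_now, float(cycles))
        )
        _apply_feedback(state, matching, float(feedback), params, rng)
        _relax(state, dyn)
        prev_resp = response
    return trials


def _run_brxt_session(params: ModelParams, rng: np.random.Generator, pid: str) -> List[TrialRecord]:
    dyn = params.dynamics
    spec = build_brxt_sequence(seed=rng)
    other_rule = str(rng.choice(DISTRACTOR_RULES))  # the per-participant fifth schema
    cog_rules = BRXT_KNOWN_RULES + (other_rule,)
    n_cog, n_sma = len(cog_rules), N_POSITIONS
    state = init_state(n_cog, n_sma, params)
    trials: List[TrialRecord] = []
    prev_stim: Optional[int] = None
    prev_resp = 0
    for t in range(1, len(spec.target_sequence) + 1):
        stim = brxt_stimulus(spec, t)
        target = spec.target_sequence[t - 1]
        routing = np.zeros((n_cog, n_sma))
        for j, rule in enumerate(cog_rules):
            routing[j, brxt_next_target(rule, stim) - 1] = 1.0
        bu = rng.uniform(-dyn.sma_bias_half, dyn.sma_bias_half, n_sma)
        bu[stim - 1] += dyn.brxt_stim_in
        if prev_resp:
            bu[prev_resp - 1] += dyn.w_prime
        cog_drive = _cog_drive(state, dyn, rng)
        if prev_stim is not None:
            # rules that link the two most recent filled disks receive
            # bottom-up activation (the model's rule-induction channel)
            for j, rule in enumerate(cog_rules):
                if brxt_next_target(rule, prev_stim) == stim:
                    cog_drive[j] += dyn.cog_bonus
        inputs = TrialInputs(cog_drive, bu, routing)
        widx, cycles, _ = select_and_respond(state, inputs, params, rng)
        response = widx + 1
        feedback = 1 if response == target else -1
        # a rule matches iff it links the two most recent positions in play:
        # the filled disk and the response it produced (response-consistency,
        # exactly parallel to the card-sorting contingency)
        matching = np.array([brxt_next_target(rule, stim) == response for rule in cog_rules])
        trials.append(
            TrialRecord(pid, "brxt", t, str(stim), response, target,
                        feedback, spec.active_rule(t), float(cycles))
        )
        _apply_feedback(state, matching, float(feedback), params, rng)
        _relax(state, dyn)
        prev_stim = stim
        prev_resp = response
    return trials


def run_session(
    task: str,
    params: ModelParams,
    seed: SeedLike,
    participant_id: str = "sim",
) -> List[TrialRecord]:
    """Run one full simulated session of ``task`` (64 or 50 trials)."""
    rng = as_rng(seed)
    if task == "wcst":
        return _run_wcst_session(params, rng, participant_id)
    if task == "brxt":
        return _run_brxt_session(params, rng, participant_id)
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# Group-level runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Per-measure mean/SD for a (simulated or empirical) group of size ``n``."""

    measures: Dict[str, Tuple[float, float]]
    n: int

    def mean(self, m: str) -> float:
        return self.measures[m][0]

    def sd(self, m: str) -> float:
        return self.measures[m][1]

    @property
    def measure_names(self) -> Tuple[str, ...]:
        return tuple(self.measures)


@dataclass(frozen=True)
class GroupResult:
    summary: GroupSummary
    scores: pd.DataFrame             # one row per simulated run
    rt_after_pos: float              # mean cycles on trials after positive feedback
    rt_after_neg: float


TASK_MEASURES = {
    "wcst": ("TE", "PE", "SL3", "CA"),
    "brxt": ("TE", "PSTIM", "PRESP", "PRULE"),
}


def run_group(
    task: str,
    params: ModelParams,
    n: int = 25,
    seed: SeedLike = None,
) -> GroupResult:
    """Run ``n`` independent sessions and summarize scores and RT by prior feedback."""
    if n < 2:
        raise ValueError("need n >= 2 simulated runs")
    rng = as_rng(seed)
    rows = []
    rt_pos_means, rt_neg_means = [], []
    for k in range(n):
        trials = run_session(task, params, rng, participant_id=f"sim_{k + 1:03d}")
        if task == "wcst":
            scores = vars(score_wcst(trials))
        else:
            scores = vars(score_brxt(trials))
        rows.append(scores)
        rt_p, rt_n = rt_by_prior_feedback(trials)
        rt_pos_means.append(rt_p)
        rt_neg_means.append(rt_n)
    scores_df = pd.DataFrame(rows)
    measures = {
        m: (float(scores_df[m].mean()), float(scores_df[m].std(ddof=1)))
        for m in TASK_MEASURES[task]
    }
    return GroupResult(
        summary=GroupSummary(measures=measures, n=n),
        scores=scores_df,
        rt_after_pos=float(np.nanmean(rt_pos_means)),
        rt_after_neg=float(np.nanmean(rt_neg_means)),
    )
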