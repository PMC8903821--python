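"""Deterministic task environments: card sorting (WCST) and spatial anticipation (BRXT).

The card-sorting environment deals all 64 number x color x shape
combinations against four fixed target piles, switching the covert sorting
rule after every run of six correct responses.  The spatial-anticipation
environment moves a filled disk around a 9-position circle under five
sequential covert rules, ten trials each.

Both environments are purely logical: no rendering, no card removal, no
touch handling.  Out-of-bounds responses are represented upstream by the
``OUT_OF_BOUNDS`` sentinel of :mod:`schemabg.records`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

SeedLike = Union[None, int, np.random.Generator]


def as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# WCST
# ---------------------------------------------------------------------------

NUMBERS = (1, 2, 3, 4)
COLORS = ("red", "green", "yellow", "blue")
SHAPES = ("triangle", "star", "cross", "circle")

#: the three sorting dimensions, in the default rule-cycle order
WCST_DIMENSIONS = ("color", "shape", "number")


@dataclass(frozen=True)
class Card:
    """A stimulus card: a number/color/shape triple."""

    number: int
    color: str
    shape: str

    def __post_init__(self) -> None:
        if self.number not in NUMBERS:
            raise ValueError(f"number {self.number!r} not in {NUMBERS}")
        if self.color not in COLORS:
            raise ValueError(f"color {self.color!r} not in {COLORS}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape {self.shape!r} not in {SHAPES}")

    def feature(self, dimension: str) -> object:
        if dimension not in WCST_DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)

    def encode(self) -> str:
        return f"{self.number}:{self.color}:{self.shape}"

    @classmethod
    def decode(cls, text: str) -> "Card":
        number, color, shape = text.split(":")
        return cls(int(number), color, shape)


#: the four fixed target cards, indexed by pile 1..4
TARGET_CARDS: Dict[int, Card] = {
    1: Card(1, "red", "triangle"),
    2: Card(2, "green", "star"),
    3: Card(3, "yellow", "cross"),
    4: Card(4, "blue", "circle"),
}


def build_wcst_deck(seed: SeedLike = None) -> List[Card]:
    """The full 64-card factorial deck; a seeded uniform shuffle if ``seed`` given.

    With ``seed=None`` the deck is returned in canonical (number, color,
    shape) lexicographic order.
    """
    deck = [Card(n, c, s) for n in NUMBERS for c in COLORS for s in SHAPES]
    if seed is not None:
        rng = as_rng(seed)
        order = rng.permutation(len(deck))
        deck = [deck[i] for i in order]
    return deck


def wcst_match_dims(card: Card, pile: int) -> Set[str]:
    """Dimensions on which ``card`` matches the target card of ``pile``."""
    if pile not in TARGET_CARDS:
        raise ValueError(f"pile {pile!r} out of range 1..4")
    target = TARGET_CARDS[pile]
    return {d for d in WCST_DIMENSIONS if card.feature(d) == target.feature(d)}


def wcst_correct_pile(card: Card, rule: str) -> int:
    """The unique pile matching ``card`` on the dimension named by ``rule``."""
    for pile, target in TARGET_CARDS.items():
        if card.feature(rule) == target.feature(rule):
            return pile
    raise AssertionError("unreachable: target features partition each dimension")


#: run length of correct responses that completes a category
RUN_LENGTH = 6
MAX_CATEGORIES = 10
DECK_SIZE = 64


@dataclass(frozen=True)
class WcstState:
    """Immutable state of a card-sorting session."""

    deck: Tuple[Card, ...]
    rule_sequence: Tuple[str, ...] = WCST_DIMENSIONS
    deck_position: int = 0
    rule_index: int = 0
    consecutive_correct: int = 0
    categories_achieved: int = 0

    @property
    def active_rule(self) -> str:
        return self.rule_sequence[self.rule_index % len(self.rule_sequence)]

    @property
    def done(self) -> bool:
        return self.deck_position >= len(self.deck)

    @property
    def current_card(self) -> Card:
        if self.done:
            raise IndexError("deck exhausted")
        return self.deck[self.deck_position]


def make_wcst_state(
    seed: SeedLike = None,
    rule_sequence: Sequence[str] = WCST_DIMENSIONS,
) -> WcstState:
    for rule in rule_sequence:
        if rule not in WCST_DIMENSIONS:
            raise ValueError(f"unknown rule {rule!r}")
    return WcstState(deck=tuple(build_wcst_deck(seed)), rule_sequence=tuple(rule_sequence))


def wcst_step(state: WcstState, response_pile: int) -> Tuple[int, WcstState]:
    """Apply one sort: feedback is +1 iff the response matches on the active rule.

    The sorting rule advances along the (cyclic) rule sequence on the sixth
    consecutive correct response; any error resets the run counter.
    """
    if state.done:
        raise IndexError("deck exhausted")
    if response_pile not in TARGET_CARDS:
        raise ValueError(f"response pile {response_pile!r} out of range 1..4")
    card = state.current_card
    correct = card.feature(state.active_rule) == TARGET_CARDS[response_pile].feature(state.active_rule)
    if correct:
        run = state.consecutive_correct + 1
        if run == RUN_LENGTH:
            nxt = replace(
                state,
                deck_position=state.deck_position + 1,
                rule_index=state.rule_index + 1,
                consecutive_correct=0,
                categories_achieved=state.categories_achieved + 1,
            )
        else:
            nxt = replace(state, deck_position=state.deck_position + 1, consecutive_correct=run)
        return +1, nxt
    return -1, replace(state, deck_position=state.deck_position + 1, consecutive_correct=0)


# ---------------------------------------------------------------------------
# BRXT
# ---------------------------------------------------------------------------

N_POSITIONS = 9
TRIALS_PER_RULE = 10
N_RULES = 5

#: circular-offset rules (position 1..9, clockwise); values are offsets mod 9
_OFFSET_RULES: Dict[str, int] = {
    "clockwise": +1,
    "counter_clockwise": -1,
    "counter_clockwise_skip": -2,
    "clockwise_skip": +2,
    "plus_three": +3,
    "minus_four": -4,
}

#: rules drawn for the per-participant "other rules" schema
DISTRACTOR_RULES = ("clockwise_skip", "mirror", "plus_three", "minus_four")

#: placeholder rule id materialized per participant from the seed
OTHER_RULE = "other"


def brxt_rule_ids() -> Tuple[str, ...]:
    return tuple(_OFFSET_RULES) + ("alternate_1_5", "walk_1_5", "mirror")


def brxt_next_target(rule: str, current_pos: int) -> int:
    """Deterministic next disk position under ``rule`` (positions 1..9, circular)."""
    if not 1 <= current_pos <= N_POSITIONS:
        raise ValueError(f"position {current_pos!r} out of range 1..{N_POSITIONS}")
    if rule in _OFFSET_RULES:
        return (current_pos - 1 + _OFFSET_RULES[rule]) % N_POSITIONS + 1
    if rule == "alternate_1_5":
        # strict alternation between the two anchor positions
        return 5 if current_pos == 1 else 1
    if rule == "walk_1_5":
        # alternative reading: a walk along positions 1..5
        return current_pos + 1 if 1 <= current_pos < 5 else 1
    if rule == "mirror":
        # reflection of the circle fixing position 9 (1<->8, 2<->7, ...)
        return 9 - current_pos if current_pos < 9 else 9
    raise KeyError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class BrxtSpec:
    """A fully materialized spatial-anticipation session specification."""

    rules: Tuple[str, ...]
    start_pos: int
    target_sequence: Tuple[int, ...]
    n_positions: int = N_POSITIONS
    trials_per_rule: int = TRIALS_PER_RULE

    def active_rule(self, trial: int) -> str:
        """Rule governing 1-based ``trial``."""
        if not 1 <= trial <= len(self.target_sequence):
            raise ValueError(f"trial {trial} out of range")
        return self.rules[(trial - 1) // self.trials_per_rule]


#: default rule program: five sequential rules drawn from the four rules of
#: the administered test (the first repeats; the exact program is not
#: published and is configurable)
DEFAULT_BRXT_RULES = (
    "clockwise",
    "counter_clockwise",
    "alternate_1_5",
    "clockwise",
    "counter_clockwise_skip",
)


def build_brxt_sequence(
    rules: Sequence[str] = DEFAULT_BRXT_RULES,
    start_pos: int = 1,
    seed: SeedLike = None,
) -> BrxtSpec:
    """Materialize a 50-target sequence: five rules, ten targets each.

    Any occurrence of ``OTHER_RULE`` is replaced by a seeded draw from
    ``DISTRACTOR_RULES`` (the per-participant idiosyncratic rule).
    """
    if len(rules) != N_RULES:
        raise ValueError(f"expected {N_RULES} rules, got {len(rules)}")
    if not 1 <= start_pos <= N_POSITIONS:
        raise ValueError(f"start position {start_pos} out of range")
    rng = as_rng(seed)
    materialized = tuple(
        str(rng.choice(DISTRACTOR_RULES)) if r == OTHER_RULE else r for r in rules
    )
    for r in materialized:
        brxt_next_target(r, 1)  # raises on unknown rule id
    targets: List[int] = []
    pos = start_pos
    for rule in materialized:
        for _ in range(TRIALS_PER_RULE):
            pos = brxt_next_target(rule, pos)
            targets.append(pos)
    return BrxtSpec(rules=materialized, start_pos=start_pos, target_sequence=tuple(targets))


def brxt_stimulus(spec: BrxtSpec, trial: int) -> int:
    """The filled-disk position shown at the start of 1-based ``trial``."""
    if trial == 1:
        return spec.start_pos
    return spec.target_sequence[trial - 2]
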