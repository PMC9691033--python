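"""Task structure: morph space, rules, congruency, stimulus sampling, block sequencing.

The task presents a stimulus morphed along two circular feature continua
(color: red--green, shape: bunny--tee) and requires a saccade to one of four
locations. Three rules map stimulus categories to responses:

* Rule 1: shape -> Axis 1 (bunny = upper-left, tee = lower-right)
* Rule 2: color -> Axis 2 (red = upper-right, green = lower-left)
* Rule 3: color -> Axis 1 (green = upper-left, red = lower-right)

Rules run in blocks; a block ends when windowed performance crosses a
threshold, the switch is cued but the new rule is hidden, and the response
axis always alternates across blocks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

#: Morph levels (percent along the circular continuum) used to generate stimuli.
MORPH_LEVELS = (0, 30, 50, 70, 100, 130, 150, 170)
PROTOTYPE_LEVELS = frozenset({0, 100})
MORPHED_LEVELS = frozenset({30, 70, 130, 170})
BOUNDARY_LEVELS = frozenset({50, 150})


def wrap_angle(angle: float) -> float:
    """Wrap an angle (radians) to the half-open interval (-pi, pi]."""
    return math.pi - (math.pi - angle) % TWO_PI


def morph_to_angle(morph: float) -> float:
    """Map a morph level in percent to its angle on the unit circle.

    The convention is ``angle = pi * (m - 100) / 100`` wrapped to (-pi, pi]:
    the 100% prototype sits at 0, the 0% prototype at +/-pi, and the category
    boundaries (50%, 150%) at -pi/2 and +pi/2.
    """
    return wrap_angle(math.pi * ((morph % 200.0) - 100.0) / 100.0)


def category_sign(morph: float) -> int:
    """Binary category of a morph level: +1 (red/bunny side), -1 (green/tee), 0 boundary.

    The +1 category is the half-circle around the 100% prototype (levels
    strictly between 50 and 150); 50%/150% are boundary levels with no
    category.
    """
    m = morph % 200.0
    if m in (50.0, 150.0):
        return 0
    return 1 if 50.0 < m < 150.0 else -1


class Feature(str, Enum):
    COLOR = "color"
    SHAPE = "shape"


class Axis(int, Enum):
    AXIS1 = 1  # upper-left / lower-right diagonal
    AXIS2 = 2  # upper-right / lower-left diagonal


class Action(str, Enum):
    UL = "UL"
    UR = "UR"
    LL = "LL"
    LR = "LR"

    @property
    def axis(self) -> Axis:
        return Axis.AXIS1 if self in (Action.UL, Action.LR) else Axis.AXIS2


#: Canonical action ordering for Q-value vectors and policy outputs.
ACTION_ORDER = (Action.UL, Action.UR, Action.LL, Action.LR)
ACTION_INDEX = {a: i for i, a in enumerate(ACTION_ORDER)}
AXIS1_INDICES = (ACTION_INDEX[Action.UL], ACTION_INDEX[Action.LR])
AXIS2_INDICES = (ACTION_INDEX[Action.UR], ACTION_INDEX[Action.LL])


class Rule(str, Enum):
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"

    @property
    def attended_feature(self) -> Feature:
        return Feature.SHAPE if self is Rule.R1 else Feature.COLOR

    @property
    def response_axis(self) -> Axis:
        return Axis.AXIS2 if self is Rule.R2 else Axis.AXIS1


# Mapping from the binary category sign of the rule-relevant feature to the
# rewarded action. Signs: color +1 = red, -1 = green; shape +1 = bunny, -1 = tee.
_RULE_ACTION = {
    Rule.R1: {1: Action.UL, -1: Action.LR},   # bunny -> UL, tee -> LR
    Rule.R2: {1: Action.UR, -1: Action.LL},   # red -> UR, green -> LL
    Rule.R3: {1: Action.LR, -1: Action.UL},   # red -> LR, green -> UL
}


@dataclass(frozen=True)
class Stimulus:
    """A color/shape morph pair, in percent of the circular continuum."""

    color_morph: float
    shape_morph: float

    @property
    def color_angle(self) -> float:
        return morph_to_angle(self.color_morph)

    @property
    def shape_angle(self) -> float:
        return morph_to_angle(self.shape_morph)

    def morph(self, feature: Feature) -> float:
        return self.color_morph if feature is Feature.COLOR else self.shape_morph


def action_for_category(rule: Rule, sign: int) -> Action:
    """Rewarded action under ``rule`` when the relevant feature has category ``sign``."""
    if sign not in (1, -1):
        raise ValueError(f"category sign must be +1 or -1, got {sign}")
    return _RULE_ACTION[rule][sign]


def correct_action(stimulus: Stimulus, rule: Rule, rng: Optional[np.random.Generator] = None) -> Action:
    """The rewarded action for ``stimulus`` under ``rule``.

    When the rule-relevant feature sits exactly on a category boundary
    (50%/150% morph), the trial's category is drawn uniformly at random, so
    boundary trials are rewarded at chance.
    """
    sign = category_sign(stimulus.morph(rule.attended_feature))
    if sign == 0:
        if rng is None:
            raise ValueError("boundary-relevant stimulus needs an rng to draw its category")
        sign = 1 if rng.random() < 0.5 else -1
    return action_for_category(rule, sign)


def stimulus_labels(stimulus: Stimulus) -> tuple[str, str, str]:
    """Categorical labels ``(color, shape, congruency)`` for a stimulus.

    Congruency compares the rewarded responses under Rules 1 and 3 (which
    share Axis 1): ``congruent`` if both rules reward the same action,
    ``incongruent`` if they differ, ``neutral`` if either feature is a
    boundary morph.
    """
    xc = category_sign(stimulus.color_morph)
    xs = category_sign(stimulus.shape_morph)
    color = {1: "red", -1: "green", 0: "neutral"}[xc]
    shape = {1: "bunny", -1: "tee", 0: "neutral"}[xs]
    if xc == 0 or xs == 0:
        congruency = "neutral"
    else:
        # R1 rewards UL iff bunny (xs=+1); R3 rewards UL iff green (xc=-1).
        congruency = "congruent" if xc * xs == -1 else "incongruent"
    return color, shape, congruency


def _build_inventory() -> tuple[tuple[Stimulus, ...], dict[str, tuple[Stimulus, ...]]]:
    """All generable stimuli and their congruency strata.

    Boundary morphs on one feature pair only with prototype morphs on the
    other feature, which yields 44 distinct stimuli from the 8 x 8 level grid.
    """
    stimuli = []
    for c, s in itertools.product(MORPH_LEVELS, MORPH_LEVELS):
        if c in BOUNDARY_LEVELS and s not in PROTOTYPE_LEVELS:
            continue
        if s in BOUNDARY_LEVELS and c not in PROTOTYPE_LEVELS:
            continue
        stimuli.append(Stimulus(float(c), float(s)))
    strata: dict[str, list[Stimulus]] = {"congruent": [], "incongruent": [], "neutral": []}
    for stim in stimuli:
        strata[stimulus_labels(stim)[2]].append(stim)
    return tuple(stimuli), {k: tuple(v) for k, v in strata.items()}


STIMULUS_INVENTORY, STIMULUS_STRATA = _build_inventory()

#: Default share of neutral (boundary-bearing) stimuli: their uniform share
#: of the 44-stimulus inventory.
DEFAULT_P_NEUTRAL = len(STIMULUS_STRATA["neutral"]) / len(STIMULUS_INVENTORY)

# Pre-split strata as (color, shape) arrays for fast sampling.
_STRATA_ARRAYS = {
    k: (np.array([s.color_morph for s in v]), np.array([s.shape_morph for s in v]))
    for k, v in STIMULUS_STRATA.items()
}


def sample_stimulus(
    rng: np.random.Generator,
    p_incongruent: float = 0.8,
    p_neutral: float = DEFAULT_P_NEUTRAL,
) -> Stimulus:
    """Draw a stimulus: congruency stratum first, then uniform within stratum.

    ``p_incongruent`` is the incongruent share among non-neutral trials;
    ``p_neutral`` the overall share of boundary-bearing stimuli.
    """
    if not 0.0 <= p_incongruent <= 1.0:
        raise ValueError(f"p_incongruent must be in [0, 1], got {p_incongruent}")
    if not 0.0 <= p_neutral < 1.0:
        raise ValueError(f"p_neutral must be in [0, 1), got {p_neutral}")
    if rng.random() < p_neutral:
        stratum = "neutral"
    elif rng.random() < p_incongruent:
        stratum = "incongruent"
    else:
        stratum = "congruent"
    colors, shapes = _STRATA_ARRAYS[stratum]
    i = rng.integers(len(colors))
    return Stimulus(colors[i], shapes[i])


@dataclass(frozen=True)
class BlockCriteria:
    """Performance criterion that ends a block.

    ``threshold`` applies to a trailing window of ``window_r13`` trials for
    Rules 1/3 and ``window_r2`` trials for Rule 2. With
    ``split_by_morph_class`` the morphed-level ({30,70,130,170}%) and
    prototype-level ({0,100}%) accuracies of the rule-relevant feature must
    each cross the threshold independently (boundary trials are excluded from
    these aggregates); otherwise pooled accuracy is used. The relaxed
    criterion, if set, additionally triggers a switch once the block exceeds
    ``relaxed_after`` trials and the trailing ``relaxed_window`` accuracy
    exceeds ``relaxed_threshold`` (Rules 1/3 only). ``max_block_len`` always
    forces a switch.
    """

    threshold: float = 0.70
    window_r13: int = 102
    window_r2: int = 51
    split_by_morph_class: bool = True
    relaxed_threshold: Optional[float] = None
    relaxed_window: Optional[int] = None
    relaxed_after: Optional[int] = None
    max_block_len: int = 500

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.window_r13 <= 0 or self.window_r2 <= 0 or self.max_block_len <= 0:
            raise ValueError("windows and max_block_len must be positive")


#: Named presets for the two animals' switching regimes.
CRITERIA_PRESETS = {
    "monkey_S": BlockCriteria(),
    "monkey_C": BlockCriteria(
        split_by_morph_class=False,
        relaxed_threshold=0.65,
        relaxed_window=75,
        relaxed_after=200,
    ),
}


def criteria_preset(name: str) -> BlockCriteria:
    try:
        return CRITERIA_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown criteria preset {name!r}; choose from {sorted(CRITERIA_PRESETS)}")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial; ``latent_*`` fields are synthetic ground truth."""

    day_id: int
    block_index: int
    trial_in_block: int
    rule: Rule
    stimulus: Stimulus
    action: Action
    reward: int
    latent_color_percept: Optional[float] = None
    latent_shape_percept: Optional[float] = None
    latent_color_sign: Optional[int] = None
    latent_shape_sign: Optional[int] = None


def _morph_class(morph: float) -> int:
    """0 = prototype, 1 = morphed, 2 = boundary."""
    m = morph % 200.0
    if m in (0.0, 100.0):
        return 0
    if m in (50.0, 150.0):
        return 2
    return 1


def _windowed_pass(
    rewards: Sequence[int],
    classes: Sequence[int],
    window: int,
    threshold: float,
    split: bool,
) -> bool:
    if len(rewards) < window:
        return False
    rw = rewards[-window:]
    if not split:
        return sum(rw) / window >= threshold
    cw = classes[-window:]
    n = [0, 0]
    k = [0, 0]
    for r, c in zip(rw, cw):
        if c == 2:  # boundary-relevant trials never enter class accuracies
            continue
        n[c] += 1
        k[c] += r
    # An absent class cannot be assessed; be conservative and do not switch.
    if n[0] == 0 or n[1] == 0:
        return False
    return k[0] / n[0] >= threshold and k[1] / n[1] >= threshold


def switch_due_from_arrays(
    rewards: Sequence[int],
    relevant_classes: Sequence[int],
    rule: Rule,
    criteria: BlockCriteria,
) -> bool:
    """Fast core of :func:`block_switch_due` over parallel reward/class arrays."""
    n = len(rewards)
    if n >= criteria.max_block_len:
        return True
    window = criteria.window_r2 if rule is Rule.R2 else criteria.window_r13
    if _windowed_pass(rewards, relevant_classes, window, criteria.threshold, criteria.split_by_morph_class):
        return True
    if (
        rule is not Rule.R2
        and criteria.relaxed_threshold is not None
        and n > (criteria.relaxed_after or 0)
        and _windowed_pass(rewards, relevant_classes, criteria.relaxed_window, criteria.relaxed_threshold, False)
    ):
        return True
    return False


def block_switch_due(trials: Sequence[TrialRecord], rule: Rule, criteria: BlockCriteria) -> bool:
    """Whether the block's performance criterion is met after ``trials``.

    ``trials`` must all belong to the current block. Returns False whenever
    fewer trials than the window have accrued (blocks never end early), and
    True unconditionally at ``max_block_len``.
    """
    rewards = [t.reward for t in trials]
    classes = [_morph_class(t.stimulus.morph(rule.attended_feature)) for t in trials]
    return switch_due_from_arrays(rewards, classes, rule, criteria)


def next_rule(block_history: Sequence[Rule], rng: np.random.Generator) -> Rule:
    """Draw the next block's rule.

    The response axis always alternates, so Rule 2 follows any Axis-1 block
    and vice versa. After an Axis-2 block, Rule 1 vs Rule 3 is chosen
    pseudo-randomly, never allowing three consecutive Axis-1 blocks of the
    same rule. The first block of a day picks its axis at random.
    """
    if not block_history:
        if rng.random() < 0.5:
            return Rule.R2
        return Rule.R1 if rng.random() < 0.5 else Rule.R3
    prev = block_history[-1]
    if prev.response_axis is Axis.AXIS1:
        return Rule.R2
    axis1_rules = [r for r in block_history if r.response_axis is Axis.AXIS1]
    if len(axis1_rules) >= 2 and axis1_rules[-1] == axis1_rules[-2]:
        return Rule.R3 if axis1_rules[-1] is Rule.R1 else Rule.R1
    return Rule.R1 if rng.random() < 0.5 else Rule.R3
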