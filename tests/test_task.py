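import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ruleswitch.task import (
    ACTION_ORDER,
    BOUNDARY_LEVELS,
    CRITERIA_PRESETS,
    DEFAULT_P_NEUTRAL,
    MORPH_LEVELS,
    STIMULUS_INVENTORY,
    STIMULUS_STRATA,
    Action,
    Axis,
    BlockCriteria,
    Rule,
    Stimulus,
    TrialRecord,
    block_switch_due,
    category_sign,
    correct_action,
    morph_to_angle,
    next_rule,
    sample_stimulus,
    stimulus_labels,
    wrap_angle,
)


class TestMorphGeometry:
    @pytest.mark.parametrize(
        "morph, angle",
        [(0, math.pi), (100, 0.0), (150, math.pi / 2), (50, -math.pi / 2), (30, -0.7 * math.pi)],
    )
    def test_morph_to_angle_landmarks(self, morph, angle):
        # the two prototypes sit at 0 and +/-pi, boundaries at +/-pi/2
        assert morph_to_angle(morph) == pytest.approx(angle)

    def test_zero_morph_maps_to_half_turn(self):
        assert abs(morph_to_angle(0)) == pytest.approx(math.pi)

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_wrap_stays_in_half_open_interval(self, angle):
        wrapped = wrap_angle(angle)
        assert -math.pi < wrapped <= math.pi

    def test_morph_levels_are_modular(self):
        assert morph_to_angle(230.0) == pytest.approx(morph_to_angle(30.0))


class TestLabelsAndActions:
    def test_green_bunny_is_congruent_red_bunny_is_not(self):
        green_bunny = Stimulus(0.0, 100.0)
        red_bunny = Stimulus(100.0, 100.0)
        assert stimulus_labels(green_bunny) == ("green", "bunny", "congruent")
        assert stimulus_labels(red_bunny) == ("red", "bunny", "incongruent")

    def test_boundary_feature_labels_neutral(self):
        assert stimulus_labels(Stimulus(50.0, 0.0))[2] == "neutral"

    def test_rule_mappings_on_prototypes(self):
        bunny = Stimulus(30.0, 100.0)  # greenish bunny
        red = Stimulus(100.0, 30.0)  # red tee-ish
        assert correct_action(bunny, Rule.R1) is Action.UL
        assert correct_action(red, Rule.R3) is Action.LR
        red_bunny = Stimulus(100.0, 100.0)
        assert correct_action(red_bunny, Rule.R1) is Action.UL
        assert correct_action(red_bunny, Rule.R3) is Action.LR
        assert correct_action(red_bunny, Rule.R2) is Action.UR

    def test_correct_action_always_on_rule_axis(self, rng):
        for stim in STIMULUS_INVENTORY:
            for rule in Rule:
                action = correct_action(stim, rule, rng)
                assert action.axis is rule.response_axis

    def test_non_boundary_action_deterministic(self):
        # no rng is needed (nor consumed) away from the category boundary
        stim = Stimulus(70.0, 170.0)
        for rule in Rule:
            assert correct_action(stim, rule) is correct_action(stim, rule)

    def test_boundary_relevant_feature_is_rewarded_at_chance(self, rng):
        stim = Stimulus(50.0, 0.0)
        draws = [correct_action(stim, Rule.R2, rng) for _ in range(2000)]
        frac_ur = np.mean([a is Action.UR for a in draws])
        assert 0.45 < frac_ur < 0.55

    def test_congruency_invariant_under_joint_category_flip(self):
        # flipping both categories (morph -> morph + 100) preserves congruency
        for stim in STIMULUS_INVENTORY:
            flipped = Stimulus((stim.color_morph + 100) % 200, (stim.shape_morph + 100) % 200)
            assert stimulus_labels(stim)[2] == stimulus_labels(flipped)[2]


class TestStimulusSampling:
    def test_inventory_size_and_strata(self):
        assert len(STIMULUS_INVENTORY) == 44
        assert len(STIMULUS_STRATA["congruent"]) == 18
        assert len(STIMULUS_STRATA["incongruent"]) == 18
        assert len(STIMULUS_STRATA["neutral"]) == 8

    def test_incongruent_share_matches_default(self, rng):
        labels = [stimulus_labels(sample_stimulus(rng))[2] for _ in range(10_000)]
        non_neutral = [l for l in labels if l != "neutral"]
        frac = np.mean([l == "incongruent" for l in non_neutral])
        assert frac == pytest.approx(0.8, abs=0.02)

    def test_zero_incongruent_probability_degenerates(self, rng):
        labels = {
            stimulus_labels(sample_stimulus(rng, p_incongruent=0.0))[2] for _ in range(500)
        }
        assert "incongruent" not in labels

    def test_stratum_frequencies_pass_goodness_of_fit(self, rng):
        n = 100_000
        counts = {"congruent": 0, "incongruent": 0, "neutral": 0}
        for _ in range(n):
            counts[stimulus_labels(sample_stimulus(rng))[2]] += 1
        p_neutral = DEFAULT_P_NEUTRAL
        expected = np.array(
            [(1 - p_neutral) * 0.2, (1 - p_neutral) * 0.8, p_neutral]
        ) * n
        observed = np.array([counts["congruent"], counts["incongruent"], counts["neutral"]])
        assert stats.chisquare(observed, expected).pvalue > 1e-3

    def test_invalid_proportions_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_stimulus(rng, p_incongruent=1.2)
        with pytest.raises(ValueError):
            sample_stimulus(rng, p_neutral=1.0)


def _records(rewards, morphs, rule=Rule.R1):
    stim_for = {0: Stimulus(0.0, 100.0), 1: Stimulus(30.0, 130.0), 2: Stimulus(0.0, 50.0)}
    recs = []
    for i, (r, m) in enumerate(zip(rewards, morphs)):
        stim = stim_for[m]
        if rule is not Rule.R1:  # put the class on the color feature instead
            stim = Stimulus(stim.shape_morph, stim.color_morph)
        recs.append(
            TrialRecord(0, 0, i + 1, rule, stim, Action.UL, r)
        )
    return recs


class TestBlockSwitch:
    def test_perfect_window_switches(self):
        trials = _records([1] * 102, [0, 1] * 51)
        assert block_switch_due(trials, Rule.R1, CRITERIA_PRESETS["monkey_S"])

    def test_just_below_threshold_does_not_switch(self):
        # 71/102 = 69.6% < 70%
        rewards = [1] * 71 + [0] * 31
        trials = _records(rewards, [0, 1] * 51)
        assert not block_switch_due(trials, Rule.R1, BlockCriteria(split_by_morph_class=False))

    def test_split_criterion_requires_both_classes(self):
        # morphed class at 72% but prototype class at 68% -> no switch
        morphs, rewards = [], []
        for i in range(51):
            morphs += [1, 0]
            rewards += [1 if i < 37 else 0, 1 if i < 35 else 0]  # 37/51=72.5%, 35/51=68.6%
        trials = _records(rewards, morphs)
        assert not block_switch_due(trials, Rule.R1, CRITERIA_PRESETS["monkey_S"])
        rewards_ok = rewards.copy()
        # raising the prototype class above threshold makes it switch
        idx = [i for i, (m, r) in enumerate(zip(morphs, rewards)) if m == 0 and r == 0]
        for i in idx[:3]:
            rewards_ok[i] = 1
        assert block_switch_due(_records(rewards_ok, morphs), Rule.R1, CRITERIA_PRESETS["monkey_S"])

    def test_fewer_trials_than_window_never_switches(self):
        trials = _records([1] * 50, [0, 1] * 25)
        assert not block_switch_due(trials, Rule.R1, CRITERIA_PRESETS["monkey_S"])

    def test_rule2_uses_short_window(self):
        trials = _records([1] * 51, [0, 1] * 26, rule=Rule.R2)
        assert block_switch_due(trials[:51], Rule.R2, CRITERIA_PRESETS["monkey_S"])

    def test_relaxed_criterion_for_monkey_c(self):
        # 66% pooled over the whole block: below 70% but above the relaxed 65%
        rewards = ([1, 1, 0] * 84)[:250]
        trials = _records(rewards, ([0, 1] * 125)[:250])
        crit = CRITERIA_PRESETS["monkey_C"]
        assert block_switch_due(trials, Rule.R1, crit)
        assert not block_switch_due(trials[:150], Rule.R1, crit)

    def test_max_block_len_forces_switch(self):
        crit = BlockCriteria(max_block_len=10)
        trials = _records([0] * 10, [0, 1] * 5)
        assert block_switch_due(trials, Rule.R1, crit)


class TestRuleSequencing:
    def test_axis_always_alternates_and_rule2_twice_as_frequent(self, rng):
        history = []
        for _ in range(10_000):
            history.append(next_rule(history, rng))
        axes = [r.response_axis for r in history]
        assert all(a != b for a, b in zip(axes, axes[1:]))
        counts = {r: sum(h is r for h in history) for r in Rule}
        assert counts[Rule.R2] == pytest.approx(2 * counts[Rule.R1], rel=0.15)
        assert counts[Rule.R2] == pytest.approx(2 * counts[Rule.R3], rel=0.15)

    def test_no_three_consecutive_axis1_rules(self, rng):
        history = []
        for _ in range(10_000):
            history.append(next_rule(history, rng))
        axis1 = [r for r in history if r.response_axis is Axis.AXIS1]
        for a, b, c in zip(axis1, axis1[1:], axis1[2:]):
            assert not (a == b == c)

    def test_forced_alternation_after_repeat(self, rng):
        history = [Rule.R1, Rule.R2, Rule.R1, Rule.R2]
        for _ in range(50):
            assert next_rule(history, rng) is Rule.R3
        assert next_rule([Rule.R1], rng) is Rule.R2
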