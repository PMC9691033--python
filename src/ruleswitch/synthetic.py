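"""Synthetic behavioral sessions: the task loop closed over a model agent.

A simulated day is a sequence of blocks with alternating response axes.
Each trial samples a stimulus (80% incongruent among non-neutral trials by
default), corrupts it into a percept, asks the agent for action values,
samples an action from the epsilon-greedy softmax policy, scores it against
the rule's correct action, and feeds the outcome back to the agent. Blocks
end when the windowed performance criterion is met (or at the block-length
cap), and the agent's block reset runs at each switch.

Latent ground truth (percept angles and the category draws that resolved
boundary stimuli) is stored alongside each trial so analyses and likelihood
code can be validated against it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from ruleswitch.agents import (
    HQLParams,
    IOParams,
    PolicyParams,
    QLParams,
    make_agent,
    select_action,
)
from ruleswitch.perception import perceive
from ruleswitch.task import (
    Action,
    Axis,
    BlockCriteria,
    Rule,
    Stimulus,
    _morph_class,
    action_for_category,
    category_sign,
    criteria_preset,
    next_rule,
    sample_stimulus,
    switch_due_from_arrays,
    DEFAULT_P_NEUTRAL,
)

SESSION_COLUMNS = [
    "day_id",
    "block_index",
    "trial_in_block",
    "rule",
    "color_morph",
    "shape_morph",
    "action",
    "reward",
]
LATENT_COLUMNS = [
    "latent_color_percept",
    "latent_shape_percept",
    "latent_color_sign",
    "latent_shape_sign",
]

ParamBundle = Union[QLParams, IOParams, HQLParams]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic session, seed included."""

    model: str
    params: ParamBundle
    criteria: Union[BlockCriteria, str] = "monkey_S"
    blocks_per_day: int = 14
    p_incongruent: float = 0.8
    p_neutral: float = DEFAULT_P_NEUTRAL
    policy: PolicyParams = field(default_factory=PolicyParams)
    seed: int = 0

    def __post_init__(self):
        if self.blocks_per_day < 2:
            raise ValueError("blocks_per_day must be at least 2")
        if isinstance(self.criteria, str):
            object.__setattr__(self, "criteria", criteria_preset(self.criteria))

    def digest(self) -> str:
        """Stable hash of the generating configuration (provenance stamp)."""
        payload = {
            "model": self.model,
            "params": {
                k: (list(v) if isinstance(v, np.ndarray) else v)
                for k, v in vars(self.params).items()
            },
            "criteria": vars(self.criteria),
            "blocks_per_day": self.blocks_per_day,
            "p_incongruent": self.p_incongruent,
            "p_neutral": self.p_neutral,
            "policy": vars(self.policy),
            "seed": self.seed,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SessionTable:
    """Ordered trial records for one or more days plus provenance metadata."""

    frame: pd.DataFrame
    config_hash: str = ""
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.frame)


def as_frame(sessions) -> pd.DataFrame:
    """Accept a SessionTable, a DataFrame, or a list of either; return one frame."""
    if isinstance(sessions, SessionTable):
        return sessions.frame
    if isinstance(sessions, pd.DataFrame):
        return sessions
    frames = [as_frame(s) for s in sessions]
    return pd.concat(frames, ignore_index=True)


def _finalize(columns: dict, config_hash: str, seed: int) -> SessionTable:
    frame = pd.DataFrame(columns)
    frame["rule"] = frame["rule"].astype(str)
    frame["action"] = frame["action"].astype(str)
    return SessionTable(frame=frame, config_hash=config_hash, seed=seed)


def simulate_day(
    config: SimulationConfig,
    day_id: int = 0,
    rng: Optional[np.random.Generator] = None,
    state_hook: Optional[Callable] = None,
) -> SessionTable:
    """Simulate one day of ``blocks_per_day`` alternating-axis blocks.

    ``state_hook(block_index, rule, agent)``, if given, runs at the start of
    every block (after the agent's block reset) — useful for inspecting
    internal state such as weight trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    agent = make_agent(config.model, config.params, config.policy)
    agent.day_start()
    percept_params = config.params.percept
    criteria = config.criteria

    cols: dict[str, list] = {c: [] for c in SESSION_COLUMNS + LATENT_COLUMNS}
    rules: list[Rule] = []
    for block_index in range(config.blocks_per_day):
        rule = next_rule(rules, rng)
        prev_axis = rules[-1].response_axis if rules else None
        rules.append(rule)
        if block_index > 0:
            agent.block_start(prev_axis)
        if state_hook is not None:
            state_hook(block_index, rule, agent)
        relevant_feature = rule.attended_feature

        rewards: list[int] = []
        classes: list[int] = []
        trial = 0
        while True:
            trial += 1
            stim = sample_stimulus(rng, config.p_incongruent, config.p_neutral)
            percept = perceive(stim, percept_params, rng)
            q = agent.action_values(percept)
            action, _ = select_action(q, config.policy, rng)

            xc = category_sign(stim.color_morph)
            xs = category_sign(stim.shape_morph)
            if xc == 0:
                xc = 1 if rng.random() < 0.5 else -1
            if xs == 0:
                xs = 1 if rng.random() < 0.5 else -1
            relevant_sign = xs if rule is Rule.R1 else xc
            reward = int(action is action_for_category(rule, relevant_sign))
            agent.update(action, reward)

            cols["day_id"].append(day_id)
            cols["block_index"].append(block_index)
            cols["trial_in_block"].append(trial)
            cols["rule"].append(rule.value)
            cols["color_morph"].append(stim.color_morph)
            cols["shape_morph"].append(stim.shape_morph)
            cols["action"].append(action.value)
            cols["reward"].append(reward)
            cols["latent_color_percept"].append(percept.color_angle)
            cols["latent_shape_percept"].append(percept.shape_angle)
            cols["latent_color_sign"].append(xc)
            cols["latent_shape_sign"].append(xs)

            rewards.append(reward)
            classes.append(_morph_class(stim.morph(relevant_feature)))
            if switch_due_from_arrays(rewards, classes, rule, criteria):
                break

    return _finalize(cols, config.digest(), config.seed)


def simulate_cohort(
    config: SimulationConfig,
    n_days: int,
    rng: Optional[np.random.Generator] = None,
) -> list[SessionTable]:
    """Simulate ``n_days`` independent days with per-day seed substreams."""
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(n_days)
    out = []
    for day, child in enumerate(children):
        out.append(simulate_day(config, day_id=day, rng=np.random.default_rng(child)))
    return out


# ---------------------------------------------------------------------------
# Deterministic unit-test fixtures


def _scripted_day(
    choose: Callable[[Rule, int, np.random.Generator], Action],
    n_blocks: int,
    block_len: int,
    seed: int,
    kind: str,
) -> SessionTable:
    """Fixed-length blocks driven by a scripted (non-learning) chooser."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols: dict[str, list] = {c: [] for c in SESSION_COLUMNS + LATENT_COLUMNS}
    rules: list[Rule] = []
    for block_index in range(n_blocks):
        rule = next_rule(rules, rng)
        rules.append(rule)
        for trial in range(1, block_len + 1):
            stim = sample_stimulus(rng)
            xc = category_sign(stim.color_morph)
            xs = category_sign(stim.shape_morph)
            if xc == 0:
                xc = 1 if rng.random() < 0.5 else -1
            if xs == 0:
                xs = 1 if rng.random() < 0.5 else -1
            relevant_sign = xs if rule is Rule.R1 else xc
            correct = action_for_category(rule, relevant_sign)
            action = choose(rule, relevant_sign, rng)
            reward = int(action is correct)
            cols["day_id"].append(0)
            cols["block_index"].append(block_index)
            cols["trial_in_block"].append(trial)
            cols["rule"].append(rule.value)
            cols["color_morph"].append(stim.color_morph)
            cols["shape_morph"].append(stim.shape_morph)
            cols["action"].append(action.value)
            cols["reward"].append(reward)
            cols["latent_color_percept"].append(stim.color_angle)
            cols["latent_shape_percept"].append(stim.shape_angle)
            cols["latent_color_sign"].append(xc)
            cols["latent_shape_sign"].append(xs)
    return _finalize(cols, f"fixture:{kind}", seed)


def generate_fixture(kind: str, seed: int = 0) -> SessionTable:
    """Tiny deterministic sessions for unit tests.

    * ``perfect_agent`` — always responds correctly (3 blocks x 20 trials).
    * ``axis1_only`` — always saccades upper-left (3 blocks x 20 trials).
    * ``three_block_mini`` — a QL agent, 3 blocks x 6 trials, latents stored.
    """
    if kind == "perfect_agent":
        return _scripted_day(
            lambda rule, sign, rng: action_for_category(rule, sign), 3, 20, seed, kind
        )
    if kind == "axis1_only":
        return _scripted_day(lambda rule, sign, rng: Action.UL, 3, 20, seed, kind)
    if kind == "three_block_mini":
        params = QLParams(kappa_color=2.0, kappa_shape=1.5, alpha=0.3)
        config = SimulationConfig(
            model="QL",
            params=params,
            criteria=BlockCriteria(max_block_len=6),
            blocks_per_day=3,
            seed=seed,
        )
        table = simulate_day(config)
        table.config_hash = f"fixture:{kind}"
        return table
    raise KeyError(f"unknown fixture kind {kind!r}")
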