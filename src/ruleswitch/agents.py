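"""The three behavioral models: QL incremental learner, IO ideal observer, HQL hybrid.

All models share the same perceptual front end (Von Mises noise) and the
same epsilon-greedy softmax policy over four action values; they differ in
how percepts are mapped to values:

* **QL** — Q-learning with linear function approximation over a binary
  feature-response basis; weights updated by the delta rule and reset to
  ``w0`` at every block switch.
* **IO** — Bayesian ideal observer holding beliefs over the three rules,
  mixing each rule's known reward likelihoods by belief, and updating
  beliefs from reward outcomes.
* **HQL** — hybrid: Bayesian beliefs over the two response axes combined
  with incrementally learned (sigmoid) reward likelihoods per action, with a
  per-trial weight decay toward asymptotic values ``w0``.

Weight vectors order the actions (UL, LR, LL, UR) with a (color, shape)
slot pair each, so the rule-target vectors are
``w_R1 = [0,1,0,-1,0,0,0,0]``, ``w_R2 = [0,0,0,0,-1,0,1,0]`` and
``w_R3 = [-1,0,1,0,0,0,0,0]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from ruleswitch.perception import CachedCategoryPosterior, Percept, PerceptParams, classify_binary
from ruleswitch.task import (
    ACTION_INDEX,
    ACTION_ORDER,
    Action,
    Axis,
    Rule,
)

#: Weight-block order of actions within the 8-vector (two slots each: color, shape).
WEIGHT_ACTION_ORDER = (Action.UL, Action.LR, Action.LL, Action.UR)
WEIGHT_SLOT = {a: i for i, a in enumerate(WEIGHT_ACTION_ORDER)}

RULE_TARGET_WEIGHTS = {
    Rule.R1: np.array([0.0, 1.0, 0.0, -1.0, 0.0, 0.0, 0.0, 0.0]),
    Rule.R2: np.array([0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 1.0, 0.0]),
    Rule.R3: np.array([-1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
}

#: Likelihood floor applied before belief renormalization; prevents a single
#: decisive outcome from annihilating a hypothesis for the rest of the block.
BELIEF_FLOOR = 1e-6


@dataclass(frozen=True)
class PolicyParams:
    """Epsilon-greedy softmax policy; both parameters are fixed, not fitted."""

    beta: float = 10.0
    epsilon: float = 0.02

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


def action_probabilities(q: np.ndarray, policy: PolicyParams) -> np.ndarray:
    """Pr(a) = eps/4 + (1-eps) * softmax(beta * q), in canonical action order."""
    q = np.asarray(q, dtype=float)
    z = policy.beta * q
    z = z - z.max()
    ez = np.exp(z)
    return policy.epsilon / 4.0 + (1.0 - policy.epsilon) * ez / ez.sum()


def select_action(
    q: np.ndarray, policy: PolicyParams, rng: np.random.Generator
) -> tuple[Action, np.ndarray]:
    """Sample an action from the policy; returns the action and the full distribution."""
    probs = action_probabilities(q, policy)
    u = rng.random()
    c = 0.0
    for i, p in enumerate(probs):
        c += p
        if u < c:
            return ACTION_ORDER[i], probs
    return ACTION_ORDER[-1], probs


def feature_response_matrix(x_color: int, x_shape: int) -> np.ndarray:
    """The 8x4 binary feature-response basis for percept classes (+/-1).

    Column ``a`` (canonical action order) carries the color and shape classes
    in action ``a``'s two weight slots and zeros elsewhere.
    """
    phi = np.zeros((8, 4))
    for action in ACTION_ORDER:
        col = ACTION_INDEX[action]
        slot = 2 * WEIGHT_SLOT[action]
        phi[slot, col] = x_color
        phi[slot + 1, col] = x_shape
    return phi


def phi_column(x_color: int, x_shape: int, action: Action) -> np.ndarray:
    """Single column of the feature-response matrix for the chosen action."""
    col = np.zeros(8)
    slot = 2 * WEIGHT_SLOT[action]
    col[slot] = x_color
    col[slot + 1] = x_shape
    return col


def ql_values(w: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Linear action values Q(a) = w . phi(:, a)."""
    return np.asarray(w) @ np.asarray(phi)


def ql_update(w: np.ndarray, phi_a: np.ndarray, reward: int, q_a: float, alpha: float) -> np.ndarray:
    """Delta rule: w <- w + alpha * (r - Q(a)) * phi_a. Touches only the chosen action's slots."""
    return np.asarray(w) + alpha * (reward - q_a) * np.asarray(phi_a)


# ---------------------------------------------------------------------------
# Ideal observer


def io_values(beliefs: np.ndarray, p_color: float, p_shape: float) -> np.ndarray:
    """Belief-weighted reward probabilities per action (canonical order UL, UR, LL, LR).

    ``p_color``/``p_shape`` are the posterior probabilities that the true
    color is red and the true shape is bunny. Rule 1 rewards UL for bunny and
    LR for tee; Rule 3 rewards LR for red and UL for green; Rule 2 rewards UR
    for red and LL for green.
    """
    b1, b2, b3 = beliefs
    return np.array(
        [
            p_shape * b1 + (1.0 - p_color) * b3,          # UL
            p_color * b2,                                  # UR
            (1.0 - p_color) * b2,                          # LL
            (1.0 - p_shape) * b1 + p_color * b3,           # LR
        ]
    )


def io_reward_likelihoods(p_color: float, p_shape: float, action: Action) -> np.ndarray:
    """Pr(r=1 | percept, action, R) for each rule; zero off the rule's axis."""
    if action is Action.UL:
        return np.array([p_shape, 0.0, 1.0 - p_color])
    if action is Action.LR:
        return np.array([1.0 - p_shape, 0.0, p_color])
    if action is Action.UR:
        return np.array([0.0, p_color, 0.0])
    return np.array([0.0, 1.0 - p_color, 0.0])


def bayes_update(beliefs: np.ndarray, reward_likelihoods: np.ndarray, reward: int,
                 floor: float = BELIEF_FLOOR) -> np.ndarray:
    """Generic floored Bayes update shared by the IO and HQL belief stages."""
    lik = reward_likelihoods if reward == 1 else 1.0 - reward_likelihoods
    post = np.maximum(lik, floor) * np.asarray(beliefs)
    total = post.sum()
    assert total > 0.0, "belief posterior vanished despite likelihood floor"
    post /= total
    # Floor the normalized posterior as well, so no hypothesis can decay
    # below ~floor over repeated one-sided evidence within a block.
    post = np.maximum(post, floor)
    return post / post.sum()


def io_update(beliefs: np.ndarray, p_color: float, p_shape: float, action: Action,
              reward: int, floor: float = BELIEF_FLOOR) -> np.ndarray:
    """Posterior over rules after observing (action, reward) for the current percept."""
    return bayes_update(beliefs, io_reward_likelihoods(p_color, p_shape, action), reward, floor)


# ---------------------------------------------------------------------------
# Parameter bundles


def _zeros8() -> np.ndarray:
    return np.zeros(8)


@dataclass(frozen=True)
class QLParams:
    kappa_color: float
    kappa_shape: float
    alpha: float
    w0: np.ndarray = field(default_factory=_zeros8)

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        object.__setattr__(self, "w0", np.asarray(self.w0, dtype=float))

    @property
    def percept(self) -> PerceptParams:
        return PerceptParams(self.kappa_color, self.kappa_shape)


@dataclass(frozen=True)
class IOParams:
    kappa_color: float
    kappa_shape: float
    b1: float
    b3: float
    prior_mode: str = "free"

    def __post_init__(self):
        if not (0.0 <= self.b1 <= 1.0 and 0.0 <= self.b3 <= 1.0):
            raise ValueError("belief parameters must be in [0, 1]")
        if self.b1 + self.b3 > 1.0:
            raise ValueError("b1 + b3 must not exceed 1")
        if self.prior_mode not in ("free", "alternating"):
            raise ValueError("prior_mode must be 'free' or 'alternating'")

    @property
    def percept(self) -> PerceptParams:
        return PerceptParams(self.kappa_color, self.kappa_shape)


@dataclass(frozen=True)
class HQLParams:
    kappa_color: float
    kappa_shape: float
    alpha: float
    b_ax: float
    eta: float
    w0: np.ndarray = field(default_factory=_zeros8)
    gradient: str = "squared_error"  # "cross_entropy" exposed for sensitivity analysis

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 <= self.b_ax <= 1.0:
            raise ValueError("b_ax must be in [0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.gradient not in ("squared_error", "cross_entropy"):
            raise ValueError("gradient must be 'squared_error' or 'cross_entropy'")
        object.__setattr__(self, "w0", np.asarray(self.w0, dtype=float))

    @property
    def percept(self) -> PerceptParams:
        return PerceptParams(self.kappa_color, self.kappa_shape)


def io_block_prior(params: IOParams, previous_axis: Optional[Axis] = None,
                   floor: float = BELIEF_FLOOR) -> np.ndarray:
    """Rule beliefs at a block start.

    Free mode always returns ``[b1, 1-b1-b3, b3]``. Alternating mode encodes
    the known axis alternation: after an Axis-1 block all mass goes to Rule 2,
    after an Axis-2 block mass is split b1:b3 between Rules 1 and 3 (floored
    and renormalized).
    """
    base = np.array([params.b1, 1.0 - params.b1 - params.b3, params.b3])
    if params.prior_mode == "free" or previous_axis is None:
        return base
    if previous_axis is Axis.AXIS1:
        masked = np.array([0.0, 1.0, 0.0])
    else:
        total = params.b1 + params.b3
        if total <= 0.0:
            masked = np.array([0.5, 0.0, 0.5])
        else:
            masked = np.array([params.b1 / total, 0.0, params.b3 / total])
    floored = np.maximum(masked, floor)
    return floored / floored.sum()


# ---------------------------------------------------------------------------
# Hybrid learner


def hql_reward_prob(w: np.ndarray, phi_a: np.ndarray, action: Action,
                    axis_hypothesis: Axis) -> float:
    """Learned reward likelihood under an axis hypothesis; zero off-hypothesis.

    Off-axis responses are never rewarded in the task, so hypotheses only
    assign reward probability to their own axis (the learned sigmoid).
    """
    if action.axis is not axis_hypothesis:
        return 0.0
    return float(expit(float(np.dot(w, phi_a))))


def hql_values(axis_beliefs: np.ndarray, w: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Q(a) = sigmoid(w . phi(:, a)) * b(axis(a)) in canonical action order."""
    sig = expit(np.asarray(w) @ np.asarray(phi))
    b = np.array([axis_beliefs[0] if a.axis is Axis.AXIS1 else axis_beliefs[1] for a in ACTION_ORDER])
    return sig * b


def hql_update(
    w: np.ndarray,
    axis_beliefs: np.ndarray,
    phi_a: np.ndarray,
    action: Action,
    reward: int,
    params: HQLParams,
    floor: float = BELIEF_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient step on the reward-likelihood weights, decay to w0, then axis Bayes update.

    The squared-error gradient carries the sigmoid slope factor p(1-p); the
    cross-entropy variant drops it (configurable for sensitivity analysis
    only).
    """
    p = float(expit(float(np.dot(w, phi_a))))
    slope = p * (1.0 - p) if params.gradient == "squared_error" else 1.0
    w_new = np.asarray(w) + params.alpha * (reward - p) * np.asarray(phi_a) * slope
    w_new = (1.0 - params.eta) * w_new + params.eta * params.w0
    lik = np.array([p if action.axis is Axis.AXIS1 else 0.0,
                    p if action.axis is Axis.AXIS2 else 0.0])
    b_new = bayes_update(axis_beliefs, lik, reward, floor)
    return w_new, b_new


# ---------------------------------------------------------------------------
# Stateful agents used by the simulator


class BaseAgent:
    """Stateful wrapper: call ``action_values`` then ``update`` once per trial."""

    model = ""

    def __init__(self, params, policy: Optional[PolicyParams] = None):
        self.params = params
        self.policy = policy or PolicyParams()
        self.day_start()

    def day_start(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def block_start(self, previous_axis: Optional[Axis] = None):
        raise NotImplementedError

    def action_values(self, percept: Percept) -> np.ndarray:
        raise NotImplementedError

    def update(self, action: Action, reward: int):
        raise NotImplementedError


class QLAgent(BaseAgent):
    """Incremental learner: weights relearned from ``w0`` every block."""

    model = "QL"

    def day_start(self):
        self.w = self.params.w0.copy()

    def block_start(self, previous_axis=None):
        self.w = self.params.w0.copy()

    def action_values(self, percept):
        self._x = (classify_binary(percept.color_angle), classify_binary(percept.shape_angle))
        self._phi = feature_response_matrix(*self._x)
        self._q = ql_values(self.w, self._phi)
        return self._q

    def update(self, action, reward):
        idx = ACTION_INDEX[action]
        self.w = ql_update(self.w, self._phi[:, idx], reward, self._q[idx], self.params.alpha)


class IOAgent(BaseAgent):
    """Ideal observer with perfect rule knowledge and Bayesian rule beliefs."""

    model = "IO"

    def __init__(self, params, policy=None):
        self._post_color = CachedCategoryPosterior(params.kappa_color)
        self._post_shape = CachedCategoryPosterior(params.kappa_shape)
        super().__init__(params, policy)

    def day_start(self):
        self.beliefs = io_block_prior(self.params, None)

    def block_start(self, previous_axis=None):
        self.beliefs = io_block_prior(self.params, previous_axis)

    def action_values(self, percept):
        self._pc = float(self._post_color(percept.color_angle))
        self._ps = float(self._post_shape(percept.shape_angle))
        return io_values(self.beliefs, self._pc, self._ps)

    def update(self, action, reward):
        self.beliefs = io_update(self.beliefs, self._pc, self._ps, action, reward)


class HQLAgent(BaseAgent):
    """Hybrid: axis beliefs reset each block, feature weights persist within a day."""

    model = "HQL"

    def day_start(self):
        self.w = self.params.w0.copy()
        self.beliefs = np.array([self.params.b_ax, 1.0 - self.params.b_ax])

    def block_start(self, previous_axis=None):
        self.beliefs = np.array([self.params.b_ax, 1.0 - self.params.b_ax])

    def action_values(self, percept):
        self._x = (classify_binary(percept.color_angle), classify_binary(percept.shape_angle))
        self._phi = feature_response_matrix(*self._x)
        return hql_values(self.beliefs, self.w, self._phi)

    def update(self, action, reward):
        idx = ACTION_INDEX[action]
        self.w, self.beliefs = hql_update(
            self.w, self.beliefs, self._phi[:, idx], action, reward, self.params
        )


AGENT_CLASSES = {"QL": QLAgent, "IO": IOAgent, "HQL": HQLAgent}
PARAM_CLASSES = {"QL": QLParams, "IO": IOParams, "HQL": HQLParams}


def make_agent(model: str, params, policy: Optional[PolicyParams] = None) -> BaseAgent:
    try:
        cls = AGENT_CLASSES[model]
    except KeyError:
        raise KeyError(f"unknown model {model!r}; choose from {sorted(AGENT_CLASSES)}")
    return cls(params, policy)
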