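"""Behavioral statistics: learning curves, axis-switch latencies, psychometrics, congruency.

All functions accept a :class:`~ruleswitch.synthetic.SessionTable`, a bare
DataFrame in the canonical session layout, or a list of either, and are pure
(same input, same output). Blocks are identified by ``(day_id, block_index)``
and trials by the 1-based ``trial_in_block``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ruleswitch.synthetic import as_frame
from ruleswitch.task import (
    Action,
    Axis,
    BOUNDARY_LEVELS,
    Feature,
    MORPHED_LEVELS,
    PROTOTYPE_LEVELS,
    Rule,
)

_AXIS_OF_ACTION = {a.value: a.axis for a in Action}
_AXIS_OF_RULE = {r.value: r.response_axis for r in Rule}
_RELEVANT_FEATURE = {r.value: r.attended_feature for r in Rule}


@dataclass
class CurveSummary:
    """Per-trial-index mean, SEM and block count, aligned to block start."""

    trial: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trial": self.trial, "mean": self.mean, "sem": self.sem, "n": self.n})


@dataclass
class PsychometricTable:
    """Accuracy by collapsed morph bin of one feature."""

    feature: str
    table: pd.DataFrame  # columns: bin, k, n, accuracy, ci_low, ci_high, empty


def _rules_arg(rules) -> list[str]:
    if rules is None:
        return [r.value for r in Rule]
    if isinstance(rules, (Rule, str)):
        rules = [rules]
    return [r.value if isinstance(r, Rule) else str(r) for r in rules]


def _with_block_key(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["_block"] = frame["day_id"].astype(str) + ":" + frame["block_index"].astype(str)
    return frame


def _congruency(frame: pd.DataFrame) -> pd.Series:
    """Vectorized congruency labels (see :func:`ruleswitch.task.stimulus_labels`)."""
    c = frame["color_morph"] % 200.0
    s = frame["shape_morph"] % 200.0
    xc = np.where(np.isin(c, [50.0, 150.0]), 0, np.where((c > 50.0) & (c < 150.0), 1, -1))
    xs = np.where(np.isin(s, [50.0, 150.0]), 0, np.where((s > 50.0) & (s < 150.0), 1, -1))
    labels = np.where(xc * xs == 0, "neutral", np.where(xc * xs == -1, "congruent", "incongruent"))
    return pd.Series(labels, index=frame.index)


def _curve(frame: pd.DataFrame, values: pd.Series, window: Optional[int]) -> CurveSummary:
    t = frame["trial_in_block"].to_numpy()
    v = values.to_numpy(dtype=float)
    if window is not None:
        keep = t <= window
        t, v = t[keep], v[keep]
    if len(t) == 0:
        raise ValueError("no trials to summarize")
    order = np.arange(1, t.max() + 1)
    n = np.bincount(t, minlength=t.max() + 1)[1:]
    total = np.bincount(t, weights=v, minlength=t.max() + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
        sem = np.sqrt(mean * (1.0 - mean) / n)
    return CurveSummary(trial=order, mean=mean, sem=sem, n=n)


def performance_curve(sessions, rule: Union[Rule, str], window: Optional[int] = None) -> CurveSummary:
    """Accuracy by trial-in-block, averaged over blocks of ``rule``.

    Trial indices present in fewer blocks simply average over those blocks
    (no imputation); neutral-feature trials count as scored (reward-based).
    """
    frame = as_frame(sessions)
    sub = frame[frame["rule"].isin(_rules_arg(rule))]
    if sub.empty:
        raise ValueError(f"no blocks of rule {rule}")
    return _curve(sub, sub["reward"], window)


def first_correct_axis(sessions, rule: Union[Rule, str, None] = None) -> pd.DataFrame:
    """Per block, the first trial whose response lies on the block's rule axis.

    Returns one row per block with columns ``first_trial`` (NaN when no
    response ever lands on the correct axis) and ``censored``.
    """
    frame = _with_block_key(as_frame(sessions))
    sub = frame[frame["rule"].isin(_rules_arg(rule))]
    rows = []
    for block, g in sub.groupby("_block", sort=False):
        rule_axis = _AXIS_OF_RULE[g["rule"].iloc[0]]
        on_axis = g["action"].map(_AXIS_OF_ACTION) == rule_axis
        hits = g.loc[on_axis, "trial_in_block"]
        rows.append(
            {
                "block": block,
                "rule": g["rule"].iloc[0],
                "first_trial": float(hits.min()) if len(hits) else math.nan,
                "censored": len(hits) == 0,
            }
        )
    return pd.DataFrame(rows)


def fraction_first_axis_within(sessions, rule, n_trials: int = 5) -> float:
    """Fraction of blocks whose first on-correct-axis response occurs by ``n_trials``."""
    latency = first_correct_axis(sessions, rule)
    return float((latency["first_trial"] <= n_trials).mean())


def first_trial_axis_fraction(sessions, axis: Axis = Axis.AXIS2, rule=None) -> float:
    """Fraction of blocks whose very first response lies on ``axis``."""
    frame = _with_block_key(as_frame(sessions))
    sub = frame[(frame["trial_in_block"] == 1) & frame["rule"].isin(_rules_arg(rule))]
    if sub.empty:
        raise ValueError("no first trials found")
    return float((sub["action"].map(_AXIS_OF_ACTION) == axis).mean())


def off_axis_curve(sessions, rule: Union[Rule, str], n_trials: Optional[int] = 50) -> CurveSummary:
    """Proportion of responses off the rule's axis by trial-in-block."""
    frame = as_frame(sessions)
    sub = frame[frame["rule"].isin(_rules_arg(rule))]
    if sub.empty:
        raise ValueError(f"no blocks of rule {rule}")
    rule_axes = sub["rule"].map(_AXIS_OF_RULE)
    off = (sub["action"].map(_AXIS_OF_ACTION) != rule_axes).astype(float)
    return _curve(sub, off, n_trials)


def off_axis_after(sessions, rule: Union[Rule, str], after: int = 20) -> float:
    """Pooled off-axis proportion over trials with index greater than ``after``."""
    frame = as_frame(sessions)
    sub = frame[frame["rule"].isin(_rules_arg(rule)) & (frame["trial_in_block"] > after)]
    if sub.empty:
        raise ValueError("no trials beyond the requested index")
    off = sub["action"].map(_AXIS_OF_ACTION) != sub["rule"].map(_AXIS_OF_RULE)
    return float(off.mean())


def window_accuracy(
    sessions,
    rules=None,
    window: Optional[int] = 50,
    congruency: Optional[str] = None,
    morph_class: Optional[str] = None,
    feature: Optional[Feature] = None,
    start: int = 1,
) -> tuple[int, int]:
    """Correct/total counts over a trial window, optionally filtered.

    ``congruency`` filters to 'congruent'/'incongruent' stimuli;
    ``morph_class`` to 'prototype'/'morphed'/'boundary' levels of ``feature``
    (defaults to each rule's relevant feature).
    """
    frame = as_frame(sessions)
    sub = frame[frame["rule"].isin(_rules_arg(rules))]
    sub = sub[sub["trial_in_block"] >= start]
    if window is not None:
        sub = sub[sub["trial_in_block"] <= start + window - 1]
    if congruency is not None:
        sub = sub[_congruency(sub) == congruency]
    if morph_class is not None:
        bins = {"prototype": PROTOTYPE_LEVELS, "morphed": MORPHED_LEVELS, "boundary": BOUNDARY_LEVELS}
        levels = bins[morph_class]
        if feature is None:
            morph = np.where(
                sub["rule"].map(lambda r: _RELEVANT_FEATURE[r]) == Feature.COLOR,
                sub["color_morph"],
                sub["shape_morph"],
            )
        else:
            morph = sub["color_morph"] if feature is Feature.COLOR else sub["shape_morph"]
        sub = sub[np.isin(np.asarray(morph) % 200.0, list(levels))]
    return int(sub["reward"].sum()), int(len(sub))


def psychometric_table(
    sessions,
    rule: Union[Rule, str],
    feature: Feature,
    window: Optional[int] = None,
    start: int = 1,
) -> PsychometricTable:
    """Accuracy collapsed over morph bins of one feature.

    Bins are prototype {0,100}%, morphed {30,70,130,170}%, boundary {50,150}%.
    Empty bins are flagged, never fabricated.
    """
    frame = as_frame(sessions)
    sub = frame[frame["rule"].isin(_rules_arg(rule))]
    sub = sub[sub["trial_in_block"] >= start]
    if window is not None:
        sub = sub[sub["trial_in_block"] <= start + window - 1]
    morph = (sub["color_morph"] if feature is Feature.COLOR else sub["shape_morph"]) % 200.0
    bins = {
        "prototype": PROTOTYPE_LEVELS,
        "morphed": MORPHED_LEVELS,
        "boundary": BOUNDARY_LEVELS,
    }
    rows = []
    for name, levels in bins.items():
        mask = np.isin(np.asarray(morph), list(levels))
        k = int(sub.loc[mask, "reward"].sum())
        n = int(mask.sum())
        if n:
            acc = k / n
            low, high = binomial_ci(k, n)
        else:
            acc = low = high = math.nan
        rows.append(
            {"bin": name, "k": k, "n": n, "accuracy": acc, "ci_low": low, "ci_high": high, "empty": n == 0}
        )
    return PsychometricTable(feature=feature.value, table=pd.DataFrame(rows))


def congruency_effect(
    sessions, rules, window: int = 50
) -> tuple[float, float, float, float]:
    """Congruent vs incongruent accuracy over the early-block window.

    Returns ``(acc_congruent, acc_incongruent, delta_pp, fisher_p)`` where
    ``delta_pp`` is the congruent-minus-incongruent difference in percentage
    points. Neutral (boundary-bearing) stimuli are excluded.
    """
    kc, nc = window_accuracy(sessions, rules, window, congruency="congruent")
    ki, ni = window_accuracy(sessions, rules, window, congruency="incongruent")
    if nc == 0 or ni == 0:
        raise ValueError("empty congruency stratum in the requested window")
    acc_c, acc_i = kc / nc, ki / ni
    p = compare_proportions(kc, nc, ki, ni)
    return acc_c, acc_i, 100.0 * (acc_c - acc_i), p


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for two binomial counts."""
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compare empty samples")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binomial_ci(k: int, n: int, level: float = 0.95, method: str = "clopper-pearson") -> tuple[float, float]:
    """Binomial proportion confidence interval (Clopper-Pearson by default)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n > 0")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    low, high = proportion_confint(k, n, alpha=1.0 - level, method=sm_method)
    return float(low), float(high)


def summarize_session(sessions, window: int = 50) -> pd.DataFrame:
    """Tidy per-rule summary used by the CLI `analyze` subcommand."""
    rows = []
    frame = as_frame(sessions)
    for rule in Rule:
        sub = frame[frame["rule"] == rule.value]
        if sub.empty:
            continue
        k, n = window_accuracy(sub, rule, window)
        latency = first_correct_axis(sub, rule)
        rows.append(
            {
                "rule": rule.value,
                "n_blocks": frame[frame["rule"] == rule.value]
                .groupby(["day_id", "block_index"])
                .ngroups,
                "n_trials": int(len(sub)),
                f"accuracy_first_{window}": k / n if n else math.nan,
                "first_trial_axis2": first_trial_axis_fraction(sub, Axis.AXIS2, rule),
                "first_correct_axis_within_5": float((latency["first_trial"] <= 5).mean()),
            }
        )
    return pd.DataFrame(rows)
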