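"""The model-characterization battery: simulation statistics for the three agents.

Each statistic is one call into :mod:`ruleswitch.analyze` over large synthetic
cohorts run at the per-animal mean fitted parameters (monkey-S presets):
axis-switch behavior after block switches, off-axis response rates,
rule-by-rule learning-speed contrasts, and congruency effects. These are the
quantities that discriminate the incremental learner, the ideal observer and
the hybrid model from one another.
"""

from __future__ import annotations

import numpy as np

from ruleswitch import analyze as az
from ruleswitch.agents import PolicyParams, action_probabilities
from ruleswitch.config import PARAMETER_PRESETS
from ruleswitch.synthetic import SimulationConfig, as_frame, simulate_cohort
from ruleswitch.task import AXIS2_INDICES, Axis, Rule

#: Days of 14 blocks per cohort: >= 2,000 blocks for QL/IO, >= 150 days for HQL.
DEFAULT_COHORT_DAYS = {"QL": 143, "IO": 143, "HQL": 150}


def first_trial_axis2_probability(policy: PolicyParams | None = None) -> float:
    """Closed-form probability that a freshly reset QL agent responds on Axis 2.

    With weights reset to zero all four action values are equal, the
    epsilon-greedy softmax is exactly uniform, and the two Axis-2 actions
    carry half the mass.
    """
    probs = action_probabilities(np.zeros(4), policy or PolicyParams())
    return float(probs[list(AXIS2_INDICES)].sum())


def simulate_reference_cohorts(seed: int, days: dict | None = None) -> dict:
    """Simulate the three models' cohorts under monkey-S task conditions."""
    days = {**DEFAULT_COHORT_DAYS, **(days or {})}
    out = {}
    for i, (model, preset) in enumerate(
        [("QL", "monkeyS_ql"), ("IO", "monkeyS_io"), ("HQL", "monkeyS_hql")]
    ):
        config = SimulationConfig(
            model=model, params=PARAMETER_PRESETS[preset], seed=int(seed) * 8 + i + 1
        )
        out[model] = simulate_cohort(config, days[model])
    return out


def _n_blocks(sessions, rules=None) -> int:
    frame = az.as_frame(sessions)
    if rules is not None:
        frame = frame[frame["rule"].isin([r.value for r in rules])]
    return int(frame.groupby(["day_id", "block_index"]).ngroups)


def battery_statistics(cohorts: dict) -> dict:
    """All battery statistics, as ``{name: {"value": ..., "n": ...}}``.

    Percentages are on the 0-100 scale; ``n`` is the number of blocks (or
    trials, for pooled accuracies) entering each statistic.
    """
    ql, io, hql = cohorts["QL"], cohorts["IO"], cohorts["HQL"]
    stats: dict[str, dict] = {}

    def acc(sessions, rules, window, **kw) -> tuple[float, int]:
        k, n = az.window_accuracy(sessions, rules, window, **kw)
        return 100.0 * k / n, n

    # --- incremental learner -------------------------------------------------
    stats["ql_first_correct_axis_within5_r1"] = {
        "value": 100.0 * az.fraction_first_axis_within(ql, Rule.R1, 5),
        "n": _n_blocks(ql, [Rule.R1]),
    }
    stats["ql_off_axis_trial20_r1"] = {
        "value": 100.0 * float(az.off_axis_curve(ql, Rule.R1, 50).mean[19]),
        "n": int(az.off_axis_curve(ql, Rule.R1, 50).n[19]),
    }
    v, n = acc(ql, [Rule.R1, Rule.R3], 50, congruency="congruent")
    stats["ql_congruent_accuracy_r13"] = {"value": v, "n": n}

    # --- ideal observer ------------------------------------------------------
    stats["io_first_trial_axis2"] = {
        "value": 100.0 * az.first_trial_axis_fraction(io, Axis.AXIS2),
        "n": _n_blocks(io),
    }
    frame_io = as_frame(io)
    after = frame_io[(frame_io["rule"] == "R1") & (frame_io["trial_in_block"] > 20)]
    stats["io_off_axis_after20_r1"] = {
        "value": 100.0 * az.off_axis_after(io, Rule.R1, 20),
        "n": int(len(after)),
    }
    v2, n2 = acc(io, Rule.R2, 50, morph_class="morphed")
    v3, n3 = acc(io, Rule.R3, 50, morph_class="morphed")
    stats["io_morphed_delta_r2_r3"] = {"value": v2 - v3, "n": n2 + n3}

    # --- hybrid learner ------------------------------------------------------
    stats["hql_first_trial_axis2_r1"] = {
        "value": 100.0 * az.first_trial_axis_fraction(hql, Axis.AXIS2, Rule.R1),
        "n": _n_blocks(hql, [Rule.R1]),
    }
    stats["hql_first_correct_axis_within5_r13"] = {
        "value": 100.0 * az.fraction_first_axis_within(hql, [Rule.R1, Rule.R3], 5),
        "n": _n_blocks(hql, [Rule.R1, Rule.R3]),
    }
    v2, n2 = acc(hql, Rule.R2, 20)
    v1, n1 = acc(hql, Rule.R1, 20)
    stats["hql_delta20_r2_r1"] = {"value": v2 - v1, "n": n1 + n2}
    v, n = acc(hql, [Rule.R1, Rule.R3], 50, congruency="incongruent")
    stats["hql_incongruent_accuracy_r13"] = {"value": v, "n": n}
    _, _, delta, _ = az.congruency_effect(hql, Rule.R2, 50)
    _, nc = az.window_accuracy(hql, Rule.R2, 50, congruency="congruent")
    _, ni = az.window_accuracy(hql, Rule.R2, 50, congruency="incongruent")
    stats["hql_congruency_delta_r2"] = {"value": delta, "n": nc + ni}

    return stats
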