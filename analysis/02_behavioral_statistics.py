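"""Behavioral statistics of the simulated models: curves, axis switching, psychometrics.

Reads the session CSVs written by 01_simulate_models.py and tabulates, per
model: the performance curve per rule, the distribution of the first
on-correct-axis trial, off-axis response proportions, and the psychometric
tables collapsed over morph bins. Writes tidy CSVs under results/.

The headline contrast: the ideal observer and the hybrid model switch onto
the correct response axis almost immediately, while the incremental learner
starts at chance (50% on Axis 2) and keeps responding off-axis for tens of
trials; only the hybrid combines that fast switch with slow Rule-1/3
relearning.
"""

from pathlib import Path

import pandas as pd

from ruleswitch import analyze as az
from ruleswitch.sessions_io import read_session
from ruleswitch.task import Feature, Rule

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for model in ("ql", "io", "hql"):
        path = RESULTS / f"sessions_{model}.csv"
        if not path.exists():
            raise SystemExit(f"missing {path}; run 01_simulate_models.py first")
        table = read_session(path)

        curves = []
        for rule in Rule:
            curve = az.performance_curve(table, rule, window=200).to_frame()
            curve.insert(0, "rule", rule.value)
            curves.append(curve)
        pd.concat(curves).to_csv(RESULTS / f"curves_{model}.csv", index=False)

        psych = []
        for rule in (Rule.R2, Rule.R3):
            tab = az.psychometric_table(table, rule, Feature.COLOR, window=50).table
            tab.insert(0, "rule", rule.value)
            psych.append(tab)
        pd.concat(psych).to_csv(RESULTS / f"psychometric_{model}.csv", index=False)

        summary = az.summarize_session(table)
        summary.insert(0, "model", model.upper())
        rows.append(summary)
        first5 = az.fraction_first_axis_within(table, [Rule.R1, Rule.R3], 5)
        print(
            f"{model.upper()}: first-trial Axis-2 {az.first_trial_axis_fraction(table):.2f}, "
            f"correct axis within 5 trials (R1/R3) {first5:.2f}, "
            f"off-axis after trial 20 in R1 {az.off_axis_after(table, Rule.R1, 20):.3f}"
        )

    pd.concat(rows, ignore_index=True).to_csv(RESULTS / "summary_by_model.csv", index=False)
    print(f"wrote per-model summaries to {RESULTS}")


if __name__ == "__main__":
    main()
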