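"""Simulate the three behavioral models under the monkey-S task regime.

Runs modest cohorts (20 days of 14 blocks) of the incremental learner (QL),
the Bayesian ideal observer (IO) and the hybrid axis-inference learner (HQL)
at the per-animal mean fitted parameters, and writes one canonical session
CSV per model under results/. Later scripts consume these files.
"""

import sys
from pathlib import Path

import pandas as pd

from ruleswitch.config import PARAMETER_PRESETS
from ruleswitch.sessions_io import write_session
from ruleswitch.synthetic import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_DAYS = 20


def main(seed: int = 2024) -> None:
    RESULTS.mkdir(exist_ok=True)
    for model, preset in [("QL", "monkeyS_ql"), ("IO", "monkeyS_io"), ("HQL", "monkeyS_hql")]:
        config = SimulationConfig(model=model, params=PARAMETER_PRESETS[preset], seed=seed)
        days = simulate_cohort(config, N_DAYS)
        merged = days[0]
        merged.frame = pd.concat([d.frame for d in days], ignore_index=True)
        out = RESULTS / f"sessions_{model.lower()}.csv"
        write_session(merged, out)
        frame = merged.frame
        print(
            f"{model}: {N_DAYS} days, {frame.groupby(['day_id','block_index']).ngroups} blocks, "
            f"{len(frame)} trials, overall accuracy {frame['reward'].mean():.3f} -> {out.name}"
        )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2024)
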