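# ruleswitch

Behavioral modeling of **rule switching vs. rule learning** in a primate
category-response task. Monkeys (and model agents) see a stimulus morphed
along two circular continua — color (red–green) and shape ("bunny"–"tee") —
and saccade to one of four targets. The hidden rule of the current block
maps one feature to one response axis:

* **Rule 1**: shape → Axis 1 (upper-left / lower-right)
* **Rule 2**: color → Axis 2 (upper-right / lower-left)
* **Rule 3**: color → Axis 1

Block switches are cued but the new rule is not, and the response axis
always alternates. The scientific question: is behavior after a switch
driven by *fast latent-state inference* (which axis is active?) or *slow
incremental relearning* of stimulus–response weights — or both at once?

The package implements the full loop for three agents sharing a Von Mises
perceptual front end (concentrations κ_C, κ_S) and an ε-greedy softmax
policy `Pr(a) = ε/4 + (1−ε)·softmax(β·Q)` (β = 10, ε = 0.02, fixed):

* **QL** — Q-learning with linear function approximation,
  `Q(a) = w·φ(x_C, x_S, a)`, delta rule `w ← w + α(r − Q)φ_a`, weights reset
  each block;
* **IO** — Bayesian ideal observer with beliefs b(R) over the three rules,
  `Q(a) = Σ_R Pr(r=1|s_K, a, R)·b(R)`, exact Bayes updates from rewards;
* **HQL** — hybrid: Bayesian beliefs over the two *axes* combined with
  learned sigmoid reward models, `Q(a) = σ(w·φ_a)·b(axis(a))`, gradient
  updates with decay toward asymptotic weights w0.

Alongside the agents: a synthetic session generator (blocked rule
structure, 80% incongruent stimulus sampling, performance-triggered
switches, full latent ground truth), a particle-filter likelihood over the
latent percepts with multi-start fitting and simulate-and-recover
validation, and the behavioral statistics battery (performance curves,
axis-switch latencies, psychometric tables, congruency contrasts, Fisher
tests, Clopper–Pearson intervals). See `docs/methods.md` for the model
equations, numerical choices, and known limitations.

## Worked example

Simulate a day of the hybrid learner at the monkey-S fitted parameter
means and summarize it:

```python
from ruleswitch import analyze as az
from ruleswitch.config import PARAMETER_PRESETS
from ruleswitch.synthetic import SimulationConfig, simulate_day
from ruleswitch.task import Rule

config = SimulationConfig(model="HQL", params=PARAMETER_PRESETS["monkeyS_hql"], seed=1)
day = simulate_day(config)
print(az.first_trial_axis_fraction(day))                       # 1.0
print(az.fraction_first_axis_within(day, [Rule.R1, Rule.R3]))  # 1.0
print(az.congruency_effect(day, [Rule.R1, Rule.R3], window=50))
# (0.915, 0.598, 31.7, 1.6e-06)
```

On this 14-block day the hybrid agent responds on Axis 2 on every first
trial after a switch (it expects the axis to change; ~93% over large
cohorts), finds the correct axis within five trials in every block, and is
far better on congruent (91.5%) than incongruent (59.8%) stimuli early in
Axis-1 blocks (Δ = +31.7 points, Fisher p ≈ 2e-6) — the three signatures
that neither pure model shows.

The numbered drivers under `analysis/` run the full comparison
(`python analysis/01_simulate_models.py`, then `02`, `03`, `04`), writing
tidy CSVs to `results/`. From a 20-day cohort per model they print, for the
first 50 trials of each block:

```
QL  R1+R3: congruent 46.14%, incongruent 60.00%, delta -13.9 pp, Fisher p = 2.9e-17
IO  R1+R3: congruent 75.50%, incongruent 74.05%, delta +1.4 pp, Fisher p = 0.33
HQL R1+R3: congruent 91.39%, incongruent 66.20%, delta +25.2 pp, Fisher p = 2.3e-74
HQL R2   : congruent 94.82%, incongruent 95.25%, delta -0.4 pp, Fisher p = 0.54
```

The incremental learner *reverses* the congruency effect (incongruent
stimuli are four times more frequent, so error-driven weights favor them),
the ideal observer shows none, and only the hybrid produces a large
positive effect on the shared axis and none on Rule 2 — because its Axis-2
weights never have to change.

There is also a small CLI (`ruleswitch simulate | fit | analyze | recover`)
over the same functions; every subcommand takes `--seed` and all outputs
embed the generating config hash.

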