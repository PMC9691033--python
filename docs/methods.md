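# Methods

## The task

Stimuli live on two circular morph continua, color (red–green) and shape
("bunny"–"tee"), sampled at the levels {0, 30, 50, 70, 100, 130, 150, 170}%.
A level `m` maps to the angle `π(m − 100)/100` wrapped to (−π, π], so the
two prototypes sit at 0 and ±π and the category boundaries (50%, 150%) at
±π/2. Boundary levels on one feature are only generated together with
prototype levels on the other, which leaves 44 distinct stimuli of the 8×8
grid: 18 congruent, 18 incongruent, 8 neutral (boundary-bearing).

Three rules map the stimulus category to a saccade:

| rule | attended feature | response axis | mapping |
|------|-----------------|---------------|---------|
| R1 | shape | Axis 1 (UL/LR) | bunny → upper-left, tee → lower-right |
| R2 | color | Axis 2 (UR/LL) | red → upper-right, green → lower-left |
| R3 | color | Axis 1 (UL/LR) | green → upper-left, red → lower-right |

Rules run in blocks ended by a windowed performance criterion (70% over the
last 102 trials for R1/R3, 51 for R2; the "monkey_S" preset requires the
morphed- and prototype-level accuracies to pass independently, the
"monkey_C" preset uses pooled accuracy plus a relaxed 65%/75-trial criterion
after 200 trials). The response axis always alternates across blocks;
within Axis-1 blocks, R1 vs R3 is drawn pseudo-randomly with no three
consecutive Axis-1 blocks of the same rule. Incongruent stimuli make up 80%
of non-neutral trials.

Choices that the task description leaves open, fixed here once:

* **Boundary rewards.** When the rule-relevant feature is a boundary morph,
  the trial's correct category is drawn uniformly, so boundary trials pay
  off at chance — consistent with a chance-level psychometric midpoint.
  Boundary trials are excluded from the morphed/prototype accuracy classes.
* **Neutral share.** The presentation frequency of boundary-bearing stimuli
  is not specified; the generator uses their uniform share of the 44-item
  inventory (8/44 ≈ 18%) and draws uniformly within each congruency stratum.
* **Block-length cap.** `max_block_len = 500` bounds blocks when an agent
  never reaches criterion (the QL model often does not).
* **First block of a day** picks its axis at random (each axis p = 1/2), so
  Rule 2 occurs twice as often as Rule 1 or 3 in the long run.

## Perception

Each feature angle is corrupted independently by Von Mises noise with
concentration κ_C (color) or κ_S (shape); κ = 0 is uniform perception and
κ = ∞ is treated exactly as noiseless. The posterior probability that the
true feature lies in the category-1 half-circle, given a percept θ, is the
mass of a Von Mises centered on θ over [−π/2, π/2]. Because the Von Mises
CDF is not analytic this mass is computed by composite Simpson quadrature
on 1024 intervals (absolute error ≲ 1e−10 for κ ≤ 50; verified against a
2^16-node oracle and against `scipy.stats.vonmises`). Simulation and
particle filtering interpolate a cached 4096-point table (error ≈ 1e−5).
Hard classification takes sign(π/2 − |θ|), ties (exactly ±π/2) classify as
+1; a sum-of-sigmoids smooth variant (default steepness 20 per radian —
there is no canonical value, so it is configurable) exists only to mirror
gradient-based fitting approximations.

## The three agents

All agents share the ε-greedy softmax policy
`Pr(a) = ε/4 + (1−ε)·softmax(β·Q)` with β = 10 and ε = 0.02 fixed (they are
unidentifiable against perceptual noise and are never fitted).

Weight vectors order the actions (UL, LR, LL, UR), one (color, shape) slot
pair each; the feature–response matrix φ(x_C, x_S) places the two percept
classes (±1) in the chosen action's slots. Under this ordering the
asymptotic rule weights are w_R1 = [0,1,0,−1,0,…], w_R2 = [0,0,0,0,−1,0,1,0],
w_R3 = [−1,0,1,0,0,…].

**QL (incremental learner).** Q(a) = w·φ(:,a); delta rule
`w ← w + α(r − Q(a))φ_a`; weights reset to w0 (zeros by default) at every
block switch.

**IO (ideal observer).** Holds beliefs b over the three rules, initialized
each block to [b1, 1−b1−b3, b3]. Action values mix each rule's known reward
likelihoods by belief, with p_C = Pr(red | percept) and p_S = Pr(bunny |
percept): Q(UL) = p_S·b(R1) + (1−p_C)·b(R3), Q(LR) = (1−p_S)·b(R1) +
p_C·b(R3), Q(UR) = p_C·b(R2), Q(LL) = (1−p_C)·b(R2) — i.e., Rule 2 owns the
Axis-2 actions, per the task definition. Beliefs update by Bayes rule on
the observed reward (off-axis actions have zero reward likelihood under a
rule). An `alternating` prior mode encodes the known axis alternation
(mass b1:b3 on R1/R3 after an Axis-2 block, all mass on R2 after Axis-1).

**HQL (hybrid).** Beliefs over the two response axes, initialized each
block to [b_ax, 1−b_ax]; reward likelihoods per action are *learned*
sigmoids, Pr(r=1 | percept, a, A) = σ(w·φ_a) gated to zero when the
action's axis differs from the hypothesis A (the printed likelihood carries
no axis dependence, but the belief update is vacuous without the gate, and
off-axis responses are never rewarded in the task). Q(a) = σ(w·φ_a)·b(axis(a)).
The weight update is the squared-error gradient
`w ← w + α(r − p)·φ_a·p(1−p)` followed by decay `w ← (1−η)w + η·w0` (a
cross-entropy variant without the p(1−p) factor is available behind a flag
for sensitivity analysis only). Weights persist across blocks within a day
and reset to w0 at day boundaries.

**Belief numerics.** Likelihoods are floored at λ = 1e−6 before the Bayes
product and the normalized posterior is floored at λ again, so no
hypothesis is ever annihilated (every belief entry stays ≥ λ/(1+3λ)) while
axis inference remains effectively instant. Beliefs are renormalized every
trial: the recursion is otherwise scale-free, and the softmax policy is not
scale-invariant.

**Parameter presets** ship the across-day mean fitted values per animal:
QL-S (κ_C 2.2, κ_S 1.3, α 0.23); IO-S (κ_C 2.4, κ_S 1.3, b1 0.091, b3 0.14);
HQL-S (κ_C 11, κ_S 5.1, α 0.23, b_ax 0.29, η 0.046,
w0 = [−0.61, 0.79, 0.77, −0.64, −0.83, 0.035, 0.74, 0.040]); and the
monkey-C counterparts.

## Synthetic sessions

The generator closes the loop: sample stimulus → Von Mises percept → agent
values → ε-greedy softmax choice → reward from the rule's correct action →
agent update, with the block criterion checked every trial and the agent's
block reset applied at each cued switch. One master seed spawns per-day
substreams (`numpy` `SeedSequence`), so any day is reproducible in
isolation and a fixed seed yields a byte-identical session table. Latent
ground truth (percept angles, the category draws resolving boundary trials)
is stored in `latent_*` columns.

What the generator does *not* emulate: reaction times, eye-movement
kinematics, motivational drift, and the animals' actual stimulus sequences.
The original analyses replayed the monkeys' own sequences under per-day
fitted parameters; this package substitutes matched-statistics synthetic
sequences at the mean parameters, so cohort statistics carry sampling
tolerances and day-heterogeneity effects are absent. Passing tests
therefore validate the implementation and the models' qualitative
signatures, not the animals' quantitative record.

## Likelihood and fitting

The per-trial percepts are latent and the agent's internal state is a
deterministic function of the percept/choice/reward history, so the session
likelihood marginalizes over percept trajectories with a particle filter:
particles carry sampled percepts and the induced state, weights accumulate
the policy probability of each observed choice, and systematic resampling
triggers when the effective sample size falls below half the particle count
(512 particles by default). Percepts are drawn by inverse-CDF transform of
a uniform base sampled once per evaluation seed, giving common random
numbers across evaluations and a surface smooth enough for derivative-free
search. With κ = ∞ the filter collapses to a single trajectory and matches
a direct forward computation to 1e−10.

Point estimation maximizes this likelihood with bounded Powell searches:
a pool of candidate starts (the box midpoint plus random draws) is screened
with single evaluations and only the best few are polished. Concentrations
are optimized on the log scale; the learning rate is kept linear because a
log scale over-weights the near-zero region, where a flat policy erases the
gradient in every other parameter (a low-α trap observed in practice).
Bounds: κ ∈ [0.05, 50], α ∈ [0.005, 1], η ∈ [0, 0.5], belief parameters ∈
[0.01, 0.98] (b1 + b3 rescaled to ≤ 0.98 if their box draw exceeds the
simplex); w0 components ∈ [−2, 2] when fitted. The convergence flag records
whether any start improved on the first initialization.

Parameter recovery simulates days at known parameters, refits each, and
reports bias, MAE, RMSE and Spearman correlation. True values are placed on
an evenly spaced (shuffled) grid over each stated range by default — a
small iid-uniform sample can cluster badly, which degrades rank statistics
for reasons unrelated to estimator quality. Recovery runs use reduced
problem sizes chosen once for this package — QL: 10 blocks/day with block
length capped at 250 trials, 256 particles, freeing α with the
concentrations held at their generating values; HQL: 10 blocks/day capped
at 200, 64 particles, freeing (b_ax, α, η) with the concentrations and w0
held at truth. Fixing the nuisance parameters isolates the identifiability
of the parameter under study: at this day size the likelihood is nearly
flat over ±0.04 around a low learning rate, so joint fits mostly add
trade-off noise. Full-size days and full free-parameter sets use the same
machinery, only slower.

## Behavioral statistics

All analyses are pure functions of the canonical session table: performance
curves by trial-in-block (mean, binomial SEM, block count; trial indices
average over the blocks that reach them, no imputation), the distribution
of the first on-correct-axis trial per block (censored when a block never
touches its axis), off-axis proportion curves, psychometric tables
collapsed over the prototype {0,100} / morphed {30,70,130,170} / boundary
{50,150} bins (empty bins flagged, never fabricated), and congruency
contrasts over an early-block window (default: first 50 trials; "early" and
"first 20" windows are explicit arguments throughout). Proportions are
compared with two-sided Fisher exact tests; binomial intervals are
Clopper–Pearson by default (the source never names its method), Wilson by
option.

## Known limitations

* The "first response on the correct axis within five trials" statistic is
  implemented literally (smallest trial index whose response lies on the
  rule's axis). For a weight-reset QL agent this is bounded below by
  1 − 0.5⁵ ≈ 97% by construction, and for the HQL agent belief collapse
  makes it ≈ 100%; reported values for these two statistics therefore sit
  far above the reference simulation statistics used in the acceptance
  battery, which must reflect a stricter (undocumented) switch criterion.
* Simulated block lengths under the monkey-S criterion exceed the animals'
  (the QL and IO models rarely clear the morphed-class threshold and run to
  the 500-trial cap); early-window statistics are insensitive to this.
* Only point estimation is provided; no posterior uncertainty, no
  hierarchical pooling across days, and no model-comparison criteria beyond
  raw log-likelihood differences.
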