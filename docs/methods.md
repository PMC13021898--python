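# Methods

This note documents the models and procedures implemented by `rsk`: what is
simulated, which parameters matter, the numerical choices, and what the
synthetic pipeline does and does not establish about real data.

## Stimulus model (`rsk.kinematogram`)

The stimulus is a crowd of `n_agents` point agents on a 2-D square arena of
`side_deg` degrees of visual angle (defaults: 100 agents, 18°).  Rendering is
deliberately out of scope: the scientific parameters — speed, size, coherence
— are all defined in visual degrees, so positions, headings and colors fully
determine the stimulus, and any presentation layer can be built on top of the
trajectory export.

Per trial:

- exactly `round(motion_coherence × n_agents)` agents are *coherent*, heading
  0 (rightward) or π (leftward); the remaining agents receive headings drawn
  once, uniformly on [0, 2π), and keep them for the whole trial (every agent
  moves on a linear path; noise directions are never resampled per frame);
- exactly `round(color_coherence × n_agents)` agents carry the majority
  color, assigned by an independent permutation so color and motion-group
  membership are statistically independent;
- initial positions are i.i.d. uniform; no minimum-separation or collision
  constraint is imposed;
- each frame displaces every agent by `speed_deg_s / fps` along its heading
  (defaults 5°/s at 75 Hz) and wraps coordinates modulo the arena side, so
  density is conserved and agents re-enter with identity preserved.

Rounding is half-up; with 100 agents and coherence grids in multiples of 5%
the counts are exact integers and rounding never engages.  A self-check
oracle (`measure_motion_coherence`) recovers the generating coherence from
trajectories by counting exactly-horizontal wrap-corrected displacements:
under continuous uniform noise headings, a noise agent is exactly horizontal
with probability zero.  `measure_speed` likewise recovers the nominal agent
speed.

## Experimental designs (`rsk.design`)

Four generators emit `ExperimentPlan`s (tidy trial tables plus metadata):

| design | task(s) | grid | trials | blocks |
|---|---|---|---|---|
| 1a | motion | 10 motion levels (5–95%) × 2 uniform colors × 6 | 120 | 2 × 60 |
| 1b | color | 5 color levels (55–95%) × 2 majorities × 6, motion 0% | 60 | 1 × 60 |
| 2 | both | 10 motion × 10 color conditions, ×4 per task | 800 | 16 × 50 |
| 3 | cued switching | fixed 75/75 coherence | 768 | 12 × 64 |

Response mapping: motion is spatially compatible (leftward → left key);
the color mapping (khaki → left by default) is counterbalanced via a flag.
*Signed distractor congruence* is the irrelevant dimension's coherence × 100,
positive when that dimension maps onto the same key as the correct response:
20 signed levels (±5…±95) in the color task, 10 (±55…±95) in the motion task.
A stimulus is treated as univalent — congruence undefined — when it has no
coherent motion or a fully uniform crowd color (design 1a's 100% color
coherence offers no competing color decision).

Ordering uses rejection sampling throughout (shuffle, check, retry with a
10⁴-attempt cap, deterministic given the seed): at most four consecutive
trials may require the same response key, and in mixed blocks at most four
consecutive trials may share a sequence type.  In design 2, the direction
assignment over the 100-stimulus grid is additionally re-drawn until every
motion level occurs both congruently and incongruently, guaranteeing all 20
signed levels; each majority × direction cell then holds exactly 25 unique
stimuli, making congruent and incongruent trials equiprobable.

Design 3 follows the sandwich layout S₁ S₂ M×8 S₂′ S₁′.  Mixed blocks hold
32 switch and 32 repeat trials split 16/16 across tasks; the first trial of a
mixed block is typed relative to the previous block's last task, so the plan
totals exactly 256 single-task (128 per task), 256 repeat and 256 switch
trials.  (Block-first trials are nevertheless always discarded by the
analysis cleaning step, which identifies them by `trial_index == 0`.)  The
cue–stimulus interval (CSI, 200 or 800 ms) is constant within a block; the
eight mixed blocks split 4/4 with a configurable order (default alternating
ABBA-style), and the four single-task blocks are assigned CSIs so each
task × CSI cell holds one 64-trial block.  The post-response blank lasts
`1000 − CSI` ms, keeping the response–stimulus interval at exactly 2000 ms
for both CSIs (timing is inspectable via `trial_timeline`).  Majority color
and direction are 32/32 in every block, which with the fixed 75/75 coherence
makes congruent:incongruent 1:1 per block.

`validate_plan` re-checks every one of these constraints on any plan
(generated or imported) and reports violations rather than raising.
`counterbalancing_assignment` cycles participants through the 8 combinations
of first task × color-mapping flip × CSI block order.

## Synthetic observer (`rsk.observer`)

No generative model of the behavior exists to copy, so the observer is the
simplest mechanism that produces every qualitative regularity the analysis
pipeline is meant to detect.  It has three stages.

**Decision stage.** A single drift-diffusion race to symmetric boundaries
±`boundary`, Euler-discretized at 1 ms (an approximation to continuous first
passage; the noiseless limit matches the closed-form `boundary/v` crossing
time to one step).  The drift is

```
v = k_task · s_target + k_distractor · s_distractor      [evidence/s]
```

with evidence signed by the response side the dimension maps to (right
positive).  Motion evidence is the motion coherence itself (0 = no signal);
color evidence is `2·(coherence − 0.5)`, so a 50% majority — an
uninformative stimulus — carries zero evidence.  With the default gains the
motion task is *dominant*: `k_distractor_in_motion_task = 0` (color never
leaks into motion decisions, the distractor-null generative target) while
`k_distractor_in_color_task > 0` (motion facilitates or interferes with
color decisions in a graded, signed fashion).  Diffusions that do not cross
within the stimulus lifetime (2000 ms minus the trial's RT penalties) are
timeouts: no response, scored as errors downstream.

**Sequential RT penalties**, additive in milliseconds so the analysis
module's mean-difference cost estimators are unbiased for the injected
constants: `mixed_block_penalty_ms` on every mixed-block trial (mixing
cost), `switch_penalty_ms` on switch trials (switch cost),
`inertia_penalty_ms` when switching *to the motion task* after an
incongruent trial (the task-set-inertia asymmetry: releasing the dominant
task from the inhibition it needed during a conflicting color trial), and
`csi_benefit_ms` subtracted from mixed-block trials at the long CSI —
applied equally to repeat and switch trials, so preparation shrinks the
mixing cost but leaves a residual switch cost.

**Task-set intrusions.** Additive RT penalties cannot move accuracy, yet the
error costs of the task-switching literature are as robust as the RT costs
and are carried by incongruent stimuli.  The observer therefore emits, with
some probability on mixed-block trials, a response generated by the
*irrelevant* dimension's rule.  An intrusion errs exactly when the trial is
incongruent, which concentrates error costs on response-conflict stimuli
without touching correct-trial RTs.  The rate is
`intrusion_rate_short_csi` / `intrusion_rate_long_csi` on mixed-block trials
(larger with short preparation → ER-mixing cost with preparatory reduction)
plus `intrusion_rate_switch_extra` on switch trials (CSI-independent →
error cost at both CSIs with no preparatory reduction).  A small
`lapse_rate` adds uniform random responses.

Default values (tuned to reproduce sign patterns, not human magnitudes):

| parameter | default | role |
|---|---|---|
| `k_target_motion` | 7.5 /s | motion sensitivity |
| `k_target_color` | 10.5 /s | color sensitivity (on the 2c−1 scale) |
| `k_distractor_in_color_task` | 1.8 /s | motion interference on color |
| `k_distractor_in_motion_task` | 0 | task dominance |
| `boundary`, `noise_sd` | 1.0, 0.8 | speed/accuracy regime |
| `t0_ms` | 300 | non-decision time |
| `mixed_block_penalty_ms` | 100 | mixing cost |
| `switch_penalty_ms` | 40 | switch cost |
| `inertia_penalty_ms` | 35 | to-motion asymmetry after conflict |
| `csi_benefit_ms` | 30 | preparation benefit in mixed blocks |
| `intrusion_rate_short/long_csi` | 0.05 / 0.005 | ER-mixing cost + reduction |
| `intrusion_rate_switch_extra` | 0.05 | error cost |
| `lapse_rate` | 0.01 | attentional lapses |

Cost-penalty defaults are on the order of the published human effects
(switch costs of tens of ms, mixing costs of ~100 ms with a ~30 ms
preparatory reduction, a ~35 ms inertia asymmetry).  Per-participant
simulation is vectorized: one random generator per participant drives all
of that participant's diffusions, bit-reproducible given the seed.

## Analysis pipeline (`rsk.analysis`)

Cleaning drops RTs below 200 ms and block-first trials from everything;
errors and timeouts are additionally excluded from RT analyses and scored
as errors in accuracy analyses.  The filters commute, so the retained sets
are order-invariant.  RTs are natural-log transformed and accuracies
arcsine-square-root transformed; descriptives are reported back-transformed
(the back-transformed mean log RT is the geometric mean).  Accuracy
proportions are formed per participant × condition cell *before* the
transform — trial-level 0/1 arcsine is degenerate.

**Regression.** Target coherence and signed distractor congruence enter a
standardized OLS (statsmodels) per task and outcome, on observations
aggregated per participant × unique stimulus and pooled across participants
(no mixed effects — a deliberately simple model matching a single df pair
per fit).  Tests verify the coefficients against an explicit
normal-equations solve.

**Costs.** Cell means per participant × CSI × congruency × sequence type
(geometric-mean RT, raw error percentage), then switch − repeat and
repeat − single differences.  Raw error percentages are used for cost
differences; the omnibus ANOVA can run on the arcsine scale.

**Repeated-measures ANOVA.** Hand-written for arbitrary fully-crossed
within designs, because no installed package reports Greenhouse–Geisser
epsilon and partial η² for three within factors.  Each effect is projected
onto an orthonormal Kronecker contrast basis; its F statistic uses the
effect × subject interaction as the error term, ε is estimated from the
contrast covariance (clipped to [1/df, 1] and fixed at 1 for single-df
effects) and always reported, with ε-corrected p-values; η²ₚ =
SS_effect/(SS_effect+SS_error).  Sums of squares below 10⁻¹⁴ of the total
variation are treated as numerical zero.  The implementation is
cross-checked against statsmodels' `AnovaRM` (F, df, p to 1e-8) and the
paired-t identity F = t².  Post-hocs are Bonferroni-corrected pairwise
paired t-tests with family size equal to the number of pairwise
comparisons.

**Chance tests.** One-tailed one-sample t against 0.5 on the raw proportion
scale by default (arcsine optional), with Cohen's d; zero-variance inputs
are flagged as degenerate.

**Asymmetry.** Previous-trial congruency is attached within blocks before
cleaning removes any trial; switch costs are computed per CSI × switch
direction × previous congruency against the repeat trials of the same
target task and CSI (direction-matched baseline), then fed to the 2×2×2
ANOVA.  Because the inertia penalty loads on only one cell, the pure switch
penalty is estimated from the three inertia-free cells and the inertia
penalty from the to-motion previous-congruency difference.

Per-CSI cost significance uses one-sample t-tests across participants; the
"preparatory reduction" of a cost is its CSI main effect in the 2 (CSI) × 2
(congruency) ANOVA on the cost scores.  p-values are never themselves
validation targets — validation rests on recovery of injected parameters
and on type-I-error calibration.

## Orchestration and formats (`rsk.io`, `rsk.study`, `rsk.cli`)

Trial logs are versioned plain CSV (round-trip safe); parameters and run
reports are JSON.  `run_full_study` regenerates designs, simulates the
configured numbers of observers (defaults 42 for the single-task
experiments, 30 for task switching — the original sample sizes), runs each
experiment's analysis and writes tables plus a report; every output carries
a configuration hash and result directories with a foreign hash are
refused.  In the experiment-1 omnibus ANOVAs, a participant can lose every
trial of a smallest-cell condition to errors at the lowest coherences; such
empty RT cells (a fraction of a percent) are imputed with the participant's
own grand mean to keep the grid complete.  The CLI subcommands (`design`,
`simulate-stimulus`, `simulate-observer`, `validate`, `analyze`,
`run-study`) are thin wrappers over these functions, deterministic given
their seed arguments.

## Problem sizes used by the test suite

The validation suite runs the design seed sweeps at 100 seeds (40 for the
two largest designs), penalty recovery as the mean of three independent
30-participant studies, chance-test calibration over 2000 replicates of 42
participants × 12 trials, and the end-to-end sign-pattern check over 20
independent 30-participant studies — sizes chosen to keep Monte-Carlo error
well below each criterion's tolerance.

## What the synthetic pipeline does and does not show

The observer reproduces the *qualitative* regularities — psychometric
monotonicity in target coherence, a color-task-only congruence effect,
positive switch/mixing/error costs, preparation benefits without a
switch-specific preparation effect, and the to-motion inertia asymmetry —
and its injected constants are recovered by the estimators.  It does not
emulate human RT distributions beyond a broadly plausible regime, practice
or fatigue, position-in-run effects, a direction asymmetry of *error*
costs, or speed–accuracy trade-off strategies.  Passing tests therefore
establish the correctness of the designs and estimators under a known
generative model, not the human effect magnitudes, which require real data.

## Known limitations

- The diffusion is single-stage with fixed boundaries; collapsing bounds,
  leakage and inter-trial drift variability are out of scope.
- Accuracy at the default gains saturates near ceiling above ~25% motion
  coherence, so accuracy-based contrasts are uninformative there (errors
  are intrusion- and lapse-dominated at high coherence).
- Regression pools observations across participants; with strong
  between-participant heterogeneity a mixed-effects model would be
  preferable.
- The stimulus simulator is 2-D and unrendered; perceptual factors (agent
  overlap, crowding, eccentricity) have no counterpart in the model.
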