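# Methods

`viscotime` implements the analysis chain for a two-experiment
psychophysics design in which a robotic manipulandum imposes a
velocity-proportional resistive field ("viscosity", in Ns/m²) on the arm
while subjects either categorize tone durations as short/long or
reproduce them. The package's claim to test is directional: resistive
environments compress perceived duration, visible as bisection points
shifting to longer durations in categorization and constant errors
falling in reproduction. Because every analysis is paired with a seeded
generator, each stage can be validated by parameter and model recovery
without any experimental data.

## Experimental design emulated by the generators

Both tasks cross 7 tone durations with 4 viscosity levels
(0, 12, 24, 36 Ns/m²) at 10 trials per cell, i.e. 280 trials per
subject. Categorization uses log-spaced durations
{1.0, 1.26, 1.58, 2.0, 2.52, 3.17, 4.0} s in 5 blocks; reproduction
uses linearly spaced {1.0 … 4.0} s in steps of 0.5 s in 10 blocks.
Conditions are shuffled within blocks with exactly equal representation
per block; block membership is recorded but has no effect on generation.
The warm-up viscosity ramp (linear to target over 2 s, constant after)
is exposed as the pure function `viscosity_ramp`; no continuous-time
physics is simulated. All internal times are in seconds.

## Second-stage drift-diffusion model (categorization)

At tone offset, a two-boundary Wiener process with unit diffusion
coefficient decides the category: drift `v` (evidence/s, positive toward
'long'), boundary separation `a`, relative starting point `z` ('long'
boundary at 1), non-decision time `t_nd`, and optional uniform
starting-point jitter of range `sz`. Fixing the diffusion coefficient at
1 is the standard identifiability convention; it only rescales `v` and
`a` relative to tools that fix a different scale constant.

- **First-passage density.** Small-time and large-time series for the
  density at the lower boundary, switching by the standard error-bound
  criterion at truncation tolerance 1e-7; the 'long' boundary follows
  from the reflection `(v, z) -> (-v, 1-z)`. `sz > 0` is integrated by
  11-node Gauss–Legendre quadrature over the starting-point range.
- **Choice probability.** Closed form
  `P(long) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))` (`P = z` at
  `v = 0`), with the same quadrature for `sz > 0`. Written with `expm1`
  to stay stable for strongly negative drifts.
- **Simulation.** Euler–Maruyama with default step `dt = 1e-4` s
  (configurable; tests use 1e-3 where only coarse summaries matter).
  Increments are drawn in blocks of 400 steps and cumulated, so the
  Python-level loop runs ~25× per simulated second rather than 10⁴×.
  Paths unabsorbed after 60 s are redrawn with a warning. Discrete
  stepping misses within-step boundary excursions, so simulated
  absorption probabilities carry an O(√dt) bias; Monte-Carlo cross-checks
  against the closed form use `dt ≤ 2.5e-4` and 3-binomial-SE margins.
- **Likelihood.** Each response is a mixture of the Wiener joint density
  (at `rt - t_nd`) and a uniform outlier component with weight 0.05 by
  default. The uniform support is (0, max observed RT]; a right-tail
  contaminant needs a proper density and the full observed range is the
  simplest choice. An RT at or below `t_nd` with zero outlier weight
  yields an explicit infinite NLL.
- **Fitting.** Per-subject maximum likelihood with Nelder–Mead inside
  boxes (0.1 < a < 5, |v| < 6, 0.05 < z < 0.95, 0 ≤ t_nd < min RT),
  10 starts by default: one heuristic start (drift signs from choice
  fractions, t_nd at half the minimum RT) plus uniform draws. Recovery
  studies use 3 starts, which the heuristic start makes sufficient in
  practice. Hierarchical MCMC is deliberately not implemented: the
  per-condition ML route is deterministic and desk-scale, and model
  comparison uses AIC/BIC over the nested ladder
  null → v → va → vat → vatz instead of DIC. To guarantee the nested
  likelihood ordering despite local optima, `fit_model_ladder`
  warm-starts each larger model from the preceding solution and keeps
  the warm-start value if a fit ever lands above it.
- **Duration × viscosity combination.** The two marginal models (one
  varying by duration, one by viscosity) are combined by cell-wise
  arithmetic averaging of each parameter, yielding one full duration map
  per viscosity level.
- **Predictive checks.** Parameter-predictive: each draw jitters the ML
  estimates with Gaussian noise at 5% relative SD, simulates a dataset of
  the observed size, and choice proportion and mean RT per condition are
  summarized with 95% simulation bands.

The conceptual linkage between first-stage temporal accumulation and the
second stage is emulated in the generator only: the default ground truth
lets both `z` and `v` grow with log duration (gain 0.5 on `z`, 3.0 on
`v`) while viscosity subtracts `0.02 · viscosity` from the drift. The
drift decline of 0.72 across the ladder is a mid-sized effect chosen so
the bisection shift is clearly present yet single-subject recovery
remains noisy, as in real cohorts. In fitting, `(z, v)` remain free per
condition; their linkage is a testable correlation, not a constraint.

## Psychometric analysis (categorization)

Choice proportions per duration are fit by binomial maximum likelihood
with a cumulative Gumbel on natural-log duration:
`P(long|t) = guess + (1 - guess - lapse) · G((ln t - mu)/s)`,
`G(x) = 1 - exp(-exp(x))`. The log base only rescales `s`; BP and CV are
invariant to it. Guess and lapse rates are fitted but bounded to
[0, 0.1] (initialized at 0.01). The bisection point and the quartile
durations are defined on the lapse-free core curve, which makes
`CV = (t75 - t25)/(2·BP)` an exact identity of every fit; conventions
differ on whether these summaries use the lapse-adjusted or the core
curve, and the core-curve definition is recorded as this package's
choice.
All-short or all-long data produce a flagged boundary fit with the BP
outside the stimulus range and a warning rather than an error.

Downstream: per-subject OLS of BP on viscosity (closed form,
unweighted), a 10,000-resample non-parametric percentile bootstrap of
the cohort mean slope, and a median-split re-analysis that partitions
each subject × duration × viscosity cell at its median movement distance
(ties alternate between splits to keep them balanced, a convention this
package fixes since median splits leave it open) before re-fitting curves per
(subject, viscosity, split). RT outliers are removed per subject beyond
3 SD of the mean log-RT, single pass.

## Bayesian observer-actor model (reproduction)

A sample duration `t_s` yields a measurement
`t_m ~ N(t_s, (m·t_s)²)` (scalar variability), combined with a uniform
prior over the presented range ([1, 4] s for the default task) to give
the Bayes least-squares estimate `t_e = E[t_s | t_m]`; production adds
scalar noise `t_p ~ N(t_e, (p·t_e)²)`. The signed offset `b` enters at
the measurement stage (Perception variant: `t_m ~ N(t_s + b, (m·t_s)²)`)
or at the production stage (Production variant:
`t_p ~ N(t_e + b, (p·t_e)²)`); the variants coincide at `b = 0`, have
equal parameter counts, and are compared by raw NLL. Production noise
scaling with the estimate (`p·t_e`) follows the observer-actor
framework; a constant-SD alternative would be a one-line change and is
not implemented.

Numerics: the BLS integrand is evaluated in log-space on a fixed grid
over the prior support (2001 points by default); the single-trial
density marginalizes `t_m` over ±5 measurement SDs with 501 trapezoid
nodes. During fitting, one interpolation table of `t_e(t_m)` (401
points, integration grid refined as ~12·span/(m·t_min) capped at 3001)
serves all nodes of all durations at each parameter evaluation, which is
what makes per-subject fits run in seconds. Interpolation error is
far below the 1e-3 density tolerance verified in tests.

Two properties of scalar noise worth noting because they shape the
tests: (i) the BLS estimate is monotone in `t_m` only over the
physically reachable measurement range — near zero the likelihood width
`m·t_s` makes small measurements uninformative and the estimate reverts
toward the prior; (ii) even as `m → ∞` the reproduced means never
flatten completely, because the measurement *scale* itself still carries
duration information. At fixed `t_m` the large-`m` asymptote is the
1/t-weighted prior mean (≈ 2.164 s for [1, 4] s), verified against
direct quadrature.

Fitting is per viscosity (three parameters), Nelder–Mead with an
iteration cap of 3000 per start and at least 5 initializations by
default (one data-driven: Weber fractions from the reproduction CV,
offset from the mean reproduction error), inside
m, p ∈ (0.001, 1), b ∈ (−1, 1) s; the offset bound is this package's
choice. Predictive
checks default to 2 simulated datasets of 40 trials per condition from
cohort-average parameters.

The default generating parameters (m = 0.12, p = 0.08,
b = 0.05 − 0.005·viscosity s, perception variant) produce mild
overestimation at zero viscosity turning into underestimation at
36 Ns/m² — the qualitative pattern the analyses are meant to detect.
The perception-stage offset is attenuated by BLS shrinkage before it
reaches behavior, while a production-stage offset passes through
unattenuated; this asymmetry is what makes the variants distinguishable
and is verified by simulation.

## Reproduction summaries and correlation utilities

Per subject × viscosity cell, reproductions beyond 3 SD of their raw
mean are excluded in a single (hence idempotent) pass; then constant
error = mean(t_p − t_s), the central-tendency slope and intercept come
from OLS of t_p on t_s, and CV is the mean over durations of
sd(t_p)/mean(t_p) (durations with fewer than two kept trials are
skipped). Behavioral viscosity-slopes are correlated with
model-parameter viscosity-slopes via Pearson and Spearman coefficients,
and Steiger's Z for two dependent correlations sharing a variable
compares each parameter against a reference (default: largest |r|);
among the common dependent-correlation tests, Steiger's formulation is
recorded as this package's choice.

## Kinematics emulator

Per-trial movement distance is lognormal with median
`base_distance · distance_decay^viscosity` (defaults 1.0 m, 0.99 per
Ns/m², CV 0.3); summed force is
`force_base + force_gain · viscosity · distance` with mild lognormal
noise (defaults 2 N, 0.5 N per Ns/m²·m). This is deliberately the
simplest model with the right directions — expected distance strictly
falling and expected force strictly rising in viscosity — and makes no
claim about the distribution of real movements; no trajectories,
targets, or restart rules are simulated.

## What the synthetic cohorts do and do not show

Cohort generators jitter subject-level parameters lognormally (relative
SD 0.15) around the defaults. Passing recovery tests on these cohorts
shows that each estimator finds the structure its own generative model
produced at realistic trial counts (280/subject; 70 per viscosity);
it does not show robustness to model misspecification, sequential
effects, fatigue, block effects, or real kinematic-temporal coupling,
none of which the generators contain.

## Problem sizes and numerical defaults

Recovery suites in the tests run at the per-subject trial counts of the
emulated design with cohort sizes of 8–20 subjects, and the acceptance
script uses 5–10 subjects per stage; these sizes were chosen so the full
suite completes in minutes on one core while keeping every directional
assertion far from its statistical margin. Other defaults: wfpt
truncation 1e-7; Euler step 1e-4 s (simulation), 1e-3 s (bulk
summaries); BLS grid 2001; marginalization nodes 501; psychometric fits
4 starts; DDM fits 10 starts (3 in recovery loops); observer fits 5
starts (3 in recovery loops); bootstrap 10,000 resamples.

## Known limitations

- No hierarchical estimation: parameters shrink toward nothing, so
  single-subject estimates are noisier than pooled alternatives.
- The outlier-mixture support (0, max RT] differs from tools that place
  the contaminant only on the right tail; at weight 0.05 the effect on
  estimates is negligible but NLL values are not comparable across
  conventions.
- `sz` is supported in density, simulation and likelihood but disabled
  in fitting by default; enabling it adds one shared parameter.
- The observer density treats `t_p` as unbounded below (truncation at 0
  is negligible for the parameter ranges of interest); the simulator
  redraws the rare non-positive reproduction.
- Repeated-measures ANOVA / Bayes-factor reporting and hardware
  control or kinematic signal processing for real sessions are out of
  scope.
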