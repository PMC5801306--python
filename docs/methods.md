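# Methods

## The decision model

Each trial is a two-alternative forced choice modelled as a Wiener
diffusion between absorbing boundaries at 0 (incorrect) and `a`
(correct). Evidence follows `W(t+dt) = W(t) + v·dt + ε`,
`ε ~ N(0, s²·dt)` with the noise scale fixed at `s = 1` per √second, so
drift rates and boundaries in the 2–3 range are the natural magnitudes.
Because responses are coded correct/incorrect rather than left/right,
no start-point bias is identifiable and the start is fixed at `a/2`.
Observed RT is the first-passage time plus a non-decision latency `t0`
(encoding + motor), shared across trial types: the cue–stimulus
interval in the emulated design is long enough that switch preparation
is complete before the stimulus.

A fixed fraction `λ = 0.10` of responses comes from a contaminant
process instead of the diffusion. The contaminant is uniform over both
choices and over time on `(0, deadline]`: bounded support keeps the
mixture proper, and the flat RT profile absorbs fast guesses that
otherwise wreck diffusion fits. `λ` is a constant of the analysis, not
a fitted parameter; values anywhere in the 1–10% range behave
similarly, and fixing it avoids a weakly identified corner of the
parameter space.

### Likelihood evaluation

The first-passage density is evaluated with the classical small-time
and large-time series expansions of the Wiener FPT problem, choosing
per evaluation whichever series needs fewer terms for a truncation
error of 1e−7 (the standard error-bound switching rule). The upper
boundary density is the lower-boundary density with the drift sign
flipped (exact for the symmetric start). Survival mass beyond a horizon
is computed analytically by termwise integration of the large-time
series, which converges quickly at the horizons that matter here
(deadline − t0 ≳ 0.5 s).

Trials that outlast the 2-s deadline are recorded as omissions, scored
incorrect for accuracy, and removed before fitting; the diffusion
component of the likelihood is therefore renormalised to the mass that
resolves before the deadline. Normalisation, simulator agreement and
the lapse-mixture's integral are all asserted by tests (density mass
`1 ± 1e−4` over v ∈ [−5, 5], a ∈ [0.5, 4]).

### Forward simulation

Two samplers generate trials:

* **Euler–Maruyama walk** (`simulate_walks`, default dt = 1e−4 s) — the
  direct discretisation of the accumulation equation, augmented with a
  Brownian-bridge crossing test per step: even when both step endpoints
  lie inside the boundaries, the walk is absorbed with probability
  `exp(−2·d₀·d₁/dt)` (endpoint distances to the boundary). Without the
  bridge test the plain discrete check misses within-step crossings and
  delays absorption by O(√dt), which at dt = 1e−4 is already visible
  against the density (CDF deviations up to 0.012); with it the
  deviation falls to ≲ 0.005, dominated by Monte-Carlo noise.
* **Inverse-CDF sampling** (`sample_first_passage`) — draws (choice, RT)
  exactly from the density via interpolated inversion of the
  sub-distribution CDFs on a 2048-point grid, with the analytic
  survival mass as the omission probability. This is the session
  generator's default (fast, and exact up to grid interpolation); the
  Euler walk remains the independent cross-check so the two routes
  validate each other rather than sharing code.

## Synthetic study design

`SessionConfig` defaults encode the emulated design: 2 pre + 10
training + 2 post blocks × 60 trials (840 total), a switch every fourth
trial, 2-s deadline, 0.5–0.9-s ITIs, a 1-s switch cue, 600-ms speed
criterion, and six feedback conditions with the study's group sizes
(51/53/57/55/52/48 = 316). Switch trials fall on trial indices
divisible by the switch period, so every block carries
`60/4 = 15` of them; the first trial of a block has no within-block
predecessor task, is typed non-switch, and carries a `block_start` flag
that excludes it from switch-cost cells.

The generative grid places one `(v, a, t0, λ)` cell on every
(trial type, block); the default grid interpolates linearly between the
group-level block-1 and block-10 endpoints (switch: v 2.87→2.15,
a 3.22→2.45; non-switch: v 2.58→2.49, a 2.00→1.75; t0 = 0.3 s), with
pre/post blocks reusing the nearest endpoint. Between-subject
dispersion defaults to SD 0.3 on v and a (about 10–15% of the parameter
magnitudes, a typical individual-differences spread for diffusion
parameters) and 0.05 s on t0; each subject draws independent cell
offsets for v and a and a single shared t0 offset.

Feedback coins: no coins in the no-feedback and accuracy-only schemes;
otherwise 1 coin per correct response plus speed bonuses against the
600-ms criterion (switch trials: +1 within 20%, +3 within 5%;
non-switch: +1 within 5%), and −1 for incorrect or omitted responses in
the punishment-bearing schemes. Bands are one-sided (a response faster
than the criterion still earns the bonus) and tiers are exclusive
(the 5% band pays 3 bonus coins, not 3+1); both behaviours are config
switches since tier stacking in the original software is not
documented. The monetary scheme values coins at 0.2 cents; the block
scheme additionally reports percent-of-attainable coins per block.

**What the generator does *not* emulate.** Trials are exchangeable
within a cell: there are no sequential effects (post-error slowing,
task-set inertia decaying over runs), no within-block learning, no
feedback-contingent adaptation of parameters, and pre/post blocks reuse
the training grid rather than modelling novel-stimulus processes.
Passing tests therefore demonstrate that the estimation and analysis
machinery is correct and calibrated for data of this structure — not
that real task-switching data satisfy these assumptions.

A note on the generative endpoints: the four printed group-mean (v, a)
pairs imply an RT switch-cost *ratio* that rises slightly over training
(switch-trial drift and boundary fall together, leaving switch RT flat
while non-switch RT drops). Group-level endpoint grids cannot encode
the subject-level co-variation that produces a falling behavioural
switch cost, and no calibration here attempts to force one.

## Fitting

### Maximum likelihood

Per subject, all declared parameter cells are optimised jointly
(L-BFGS-B, bounds v ∈ [−8, 8], a ∈ [0.2, 6], t0 ∈ [0.03, 1.5]) from
five stratified starts: accuracy pins `v·a` through the logistic choice
identity, giving drift starts per boundary start, and an early RT
quantile anchors t0. Joint cells with fewer than 40 resolved trials
(configurable) are flagged unestimable and excluded rather than
silently fitted. Multi-seed recovery at 2,000 trials per cell is
unbiased to within ~1% at the study's parameter magnitudes. In
high-accuracy cells the boundary and t0 estimates are nearly collinear
(correlation ≈ −0.97 at the switch block-1 cell), so recovery
experiments in which t0 is a known given can pin it (`fix_t0`),
shrinking the boundary's sampling SD from ≈ 0.20 to ≈ 0.05 at n = 2000.

### Hierarchical Bayes

Subject-level parameters are partially pooled through group-level
normals: `v_{s,c} ~ N(μ_v[c], σ_v[c])` per cell (boundary and t0
likewise, on the natural scale, truncated at the fitting bounds so
group means remain directly comparable to generative values). Priors
are weakly informative at the task's magnitudes: μ_v ~ N(0, 3²),
μ_a ~ N(2, 2²), μ_t0 ~ N(0.3, 0.3²), group SDs half-normal
(scale 1, 1, 0.2).

Sampling is adaptive Metropolis-within-Gibbs with four move types per
sweep:

1. scalar random-walk updates of each subject × parameter-cell block
   (proposal scales adapted to ≈ 35% acceptance during warmup);
2. joint (v, a) proposals per cell using the running per-cell posterior
   covariance (Welford-estimated during warmup, restarted after the
   first third to drop the transient) — within a cell the likelihood
   constrains `v·a` tightly, so scalar moves alone crawl along a
   correlated ridge;
3. conjugate draws of the group means and log-scale Metropolis on the
   group SDs;
4. shift moves that translate one group mean together with every
   subject's value for that cell. In the centered parametrisation the
   group mean otherwise only moves at the pace of subject-level drift;
   the shift move is what brings split-R-hat under the threshold.

Defaults: 4 chains × (1000 warmup + 1000 draws), split-R-hat computed
per group parameter via arviz; a fit with max R-hat ≥ 1.05 is flagged
non-converged, never silently accepted. At the recovery scale used in
the tests (20 subjects × 480 trials, 20 group cells) the sampler
converges (max R-hat ≈ 1.04) in about two minutes, and all 20
group-mean 95% credible intervals cover their generative values.

### DIC

`DIC = D̄ + p_D` with `p_D = D̄ − D(θ̄)` (deviance at the posterior
means of the subject-level parameters — the classic form); the
variance-based `p_D = var(D)/2` is available behind a flag. Deviance is
accumulated from the cached per-cell log-likelihoods, so the trace
costs nothing extra. Model comparison derives each spec's sampler seed
from the master seed and the spec's name, so a duplicated spec
reproduces the identical fit and ties exactly (ties are reported and
broken by declaration order).

## Behavioural pipeline

* **Exclusion**: subjects below 80% overall training-block accuracy
  (omissions count as errors; pre/post blocks do not contribute, as
  they carry no feedback and novel stimuli) are removed and listed.
* **Block summaries**: mean RT over correct resolved trials (the
  dominant convention; a flag includes errors), accuracy =
  correct / all trials, block-start trials excluded.
* **Switch cost**: ratio switch/non-switch per subject × block
  (difference-based variant behind a flag); change scores subtract the
  last training block from the first, so positive change = cost shrank.
  Pre/post transfer uses the outermost pre/post pair for novel stimuli
  and the innermost pair for familiar stimuli.
* **Condition contrasts**: a classical split-plot ANOVA —
  between-factor Condition, within-factors Block and TrialType,
  subjects random — computed from subject × cell means, each within
  effect tested against its interaction with subjects nested in groups.
  With unequal group sizes the marginal means are subject-weighted; the
  implementation is verified against pingouin's mixed ANOVA on the
  one-within design and its type-I error is calibrated by simulation
  (condition effect fires at 4–6% under a 200-replicate null). Post-hoc
  block-1-vs-10 paired t-tests per condition and one-way ANOVAs on the
  cost changes are uncorrected by default, with a correction flag.
* **Within-subject error bars**: `within_subject_se` provides the
  Cousineau-normalised, Morey-corrected cell SEs appropriate for
  repeated-measures condition means (no plotting is bundled; the
  numbers feed whatever graphics layer the user prefers).
* **Parameter trajectories**: the same switch-cost algebra applied to
  fitted v and a per block, reporting both ratio-cost changes and raw
  first-minus-last changes (the two orderings can genuinely differ —
  see the limitation note above).

## Problem sizes in the test suite

Simulation studies are sized to run on a laptop-class core: density vs
simulator agreement at 5 × 10⁴ walks per cell (dt = 1e−4) on a 3 × 3
grid; MLE recovery at 2,000 trials per cell over 5 seeds; hierarchical
recovery at 20 subjects × 480 trials (5 training blocks); DIC selection
over 20 replicates of 5 subjects × 480 trials on a 2-block lattice;
ANOVA calibration over 200 null replicates of 16-subject cohorts. The
full suite runs in roughly a quarter hour.

## Known limitations

* No inter-trial variability parameters (drift, start, t0), no biased
  start points, no collapsing bounds — deliberately outside scope.
* The uniform lapse support `(0, deadline]` allows contaminant RTs
  below t0; that is intended (it is what makes fast guesses harmless)
  but means the lapse component is not a diffusion process.
* The adaptive joint proposals keep updating their covariance after
  warmup; adaptation diminishes as the running estimate converges,
  which is standard practice but not a formally vanishing-adaptation
  scheme.
* The mixed ANOVA uses the weighted-means solution for unbalanced
  groups; strongly unbalanced designs with missing cells should be
  analysed with a dedicated mixed-model package instead.
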