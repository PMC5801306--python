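# switchddm

Drift-diffusion modelling of task-switching training.

`switchddm` is for cognitive modellers who want to decompose
task-switching performance — reaction times *and* accuracies — into
latent decision parameters, and to ask how those parameters move over
training and under different feedback schemes. It bundles four things
behind one importable API:

1. **A session simulator** that emulates a classic task-switching
   training design: 14 blocks of 60 trials (2 pre, 10 training, 2 post),
   a rule switch every fourth trial, a 2-second response deadline, and
   six trial-wise feedback schemes (no feedback, accuracy-only,
   difficulty-aware coin bonuses against a 600-ms speed criterion,
   punishment, monetary and block-level variants).
2. **The diffusion likelihood**: a two-boundary Wiener
   first-passage-time density with the start point fixed midway between
   the boundaries, plus a fixed 10% uniform-lapse mixture that absorbs
   fast guesses.
3. **Fitting**: deterministic per-subject maximum likelihood, and
   hierarchical Bayesian estimation in which group-level distributions
   act as priors for subject-level parameters, with DIC to compare
   model variants that condition drift rate and boundary on trial type
   and training block.
4. **The behavioural pipeline**: 80%-accuracy exclusion, per-block
   summaries, ratio switch costs with block-1-minus-block-10 change
   scores, pre/post transfer contrasts, and mixed
   Block × TrialType × Condition ANOVAs with subjects as random effects.

## The model

Evidence on a trial accumulates as a random walk

```
W(t + dt) = W(t) + v·dt + ε,    ε ~ N(0, dt),    W(0) = a/2,
```

between absorbing boundaries at 0 (incorrect) and `a` (correct). The
drift rate `v` (evidence/s) indexes processing efficiency; the boundary
separation `a` indexes response caution and sets the speed–accuracy
trade-off; a non-decision time `t0` is added to the first-passage time;
the noise scale is fixed at 1 so printed parameter magnitudes of 2–3
are the natural scale. With the unbiased start, the probability of a
correct response has the closed form `P = 1/(1 + e^{−v·a})`. The
likelihood of a resolved response is the mixture

```
L(choice, t) = (1 − λ)·f_WFPT(t − t0, choice | v, a) + λ/(2·deadline),
```

with lapse rate λ = 0.10 fixed, and the diffusion mass truncated to the
deadline when omissions have been removed. Model variants declare which
of {trial type, block} condition `v` and `a`; `t0` is never conditioned
on trial type; the winning structure of the study this design follows
conditions both `v` and `a` on trial type × block.

## Worked example

`examples/mle_recovery.py` — simulate one parameter cell at the
group-level block-1 switch-trial values and recover it:

```python
from switchddm import DDMParams, simulate_trials
from switchddm.inference import ModelSpec, fit_mle

truth = DDMParams(v=2.87, a=3.22, t0=0.3, lapse=0.10)
trials = simulate_trials(truth, 2000, seed=1, trial_type="switch")
fit = fit_mle(trials, ModelSpec(), fix_t0=0.3)
```

prints

```
simulated 2000 trials, accuracy 0.957
recovered v = 2.802   (generative 2.87)
recovered a = 3.161   (generative 3.22)
```

The accuracy (0.957) is the lapse-attenuated closed form
`0.9·σ(2.87·3.22) + 0.05`; the recovered drift and boundary sit within
single-experiment sampling error (±0.15) of the generative values.

Other examples, one per capability: `simulate_cohort.py`,
`likelihood_basics.py`, `hierarchical_fit.py`, `model_comparison.py`,
`switch_cost_pipeline.py`. A thin CLI covers the shell-run entry points:

```
switchddm simulate --seed 1 --out cohort.csv
switchddm fit --data cohort.csv --model winning --mode hier --seed 1 --out fit.json
switchddm summarize --data cohort.csv --out tables/
switchddm ddm-check        # density vs simulator self-diagnostic
```

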