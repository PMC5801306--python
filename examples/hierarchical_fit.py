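"""Hierarchical Bayesian fitting on a small cohort.

Six subjects drawn around one group-level cell; the sampler pools them
and reports group-mean credible intervals with convergence diagnostics.
Runs in under a minute.
"""

import numpy as np
import pandas as pd

from switchddm import DDMParams, GenerativeGrid, simulate_trials
from switchddm.inference import ModelSpec, SamplerSettings, fit_hierarchical

grid = GenerativeGrid({("nonswitch", 1): DDMParams(2.5, 2.0, 0.3, 0.10)},
                      {"v": 0.25, "a": 0.25, "t0": 0.04})
frames = []
for i, ss in enumerate(np.random.SeedSequence(3).spawn(6)):
    rng = np.random.default_rng(ss)
    p = grid.draw_subject(rng).params[("nonswitch", 1)]
    t = simulate_trials(p, 300, seed=rng)
    t["subject_id"] = f"s{i}"
    frames.append(t)
trials = pd.concat(frames, ignore_index=True)

fit = fit_hierarchical(trials, ModelSpec(),
                       SamplerSettings(n_chains=2, n_warmup=800, n_draws=800),
                       seed=9)
print(fit.group_summary[["param", "mean", "ci_low", "ci_high", "rhat"]]
      .round(3).to_string(index=False))
print(f"\nconverged: {fit.converged} "
      f"(max split-R-hat {fit.diagnostics['max_rhat']:.3f})")
print("The 95% credible intervals for the group means should cover the "
      "generative v = 2.5 and a = 2.0; subject estimates are shrunk "
      "toward the group mean.")
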