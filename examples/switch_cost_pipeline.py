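"""The behavioural switch-cost pipeline end to end.

Simulate a small two-condition cohort, apply the 80% accuracy exclusion,
summarise per block, form ratio switch costs and run the condition
contrasts.
"""

from switchddm import SessionConfig, generate_cohort, study_grid
from switchddm.analysis import (block_summaries, condition_contrasts,
                                exclude_participants, switch_cost)

config = SessionConfig()  # the full 2 + 10 + 2 block design
cohort = generate_cohort({"NFB": 6, "PFB": 6}, study_grid(config),
                         seed=17, config=config)

retained, excluded = exclude_participants(cohort, threshold=0.80)
print(f"excluded {len(excluded)} of {cohort['subject_id'].nunique()} "
      "subjects below 80% training accuracy")

summary = block_summaries(retained)
cost = switch_cost(summary)
chg = cost.training_change
print(f"\nmean RT switch cost change (block first - last): "
      f"{chg['rt_cost_change'].mean():+.3f}")
print("  # positive = cost shrank.  On this generative grid the ratio "
      "grows slightly:\n  # the switch-trial drift falls together with "
      "its boundary, so switch RT\n  # stays flat while non-switch RT "
      "drops.")

contrasts = condition_contrasts(retained, summary, cost)
anova = contrasts.rt_anova[["effect", "F", "df1", "df2", "p"]].round(3)
print("\nmixed ANOVA on RT (Block x TrialType x Condition, "
      "subjects random):")
print(anova.to_string(index=False))
print("\nTrial type should dominate (switch trials are slower); the "
      "condition effect is whatever the feedback scheme did to speed.")
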