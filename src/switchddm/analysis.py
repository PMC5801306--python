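"""Behavioural switch-cost pipeline.

Order of operations mirrors the study's analysis: exclude subjects below
the 80% training-accuracy criterion, summarise RT and accuracy per
subject x block x trial type, form ratio switch costs
(switch / non-switch performance) with first-to-last training block
change scores, contrast feedback conditions with a mixed
Block x TrialType x Condition ANOVA (subjects random), and carry the
same switch-cost algebra onto fitted diffusion parameters to decompose
speed-accuracy trade-offs.

RT means are computed over correct resolved trials (the dominant
convention in task-switching work; a flag includes errors); accuracy
counts omissions as errors.  Block-start trials have no within-block
predecessor task and are dropped from trial-type cells by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SwitchCostTable",
    "ConditionContrasts",
    "exclude_participants",
    "block_summaries",
    "switch_cost",
    "condition_contrasts",
    "parameter_trajectories",
    "mixed_anova",
    "within_subject_se",
]


def exclude_participants(trials: pd.DataFrame, threshold: float = 0.80,
                         phases=("training",)):
    """Remove subjects whose overall accuracy over ``phases`` falls below
    ``threshold`` (omissions count as errors).

    Returns ``(retained_table, report)``; the report lists each removed
    subject with its accuracy.  Idempotent: a second application removes
    nobody."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    scope = trials[trials["block_phase"].isin(phases)]
    acc = scope.groupby("subject_id")["correct"].mean()
    removed = acc[acc < threshold]
    report = pd.DataFrame({"subject_id": removed.index,
                           "accuracy": removed.to_numpy(),
                           "threshold": threshold}).reset_index(drop=True)
    retained = trials[~trials["subject_id"].isin(set(removed.index))]
    return retained.reset_index(drop=True), report


def block_summaries(trials: pd.DataFrame, rt_trials: str = "correct",
                    include_block_start: bool = False) -> pd.DataFrame:
    """Mean RT and accuracy per subject x block x trial type.

    ``rt_trials``: "correct" averages RT over correct resolved trials
    only; "all" over every resolved trial.  Accuracy is
    correct / (correct + incorrect + omissions).  Cells with no resolved
    RT trial are flagged ``rt_missing`` (all-omission cells score
    accuracy 0)."""
    if rt_trials not in ("correct", "all"):
        raise ValueError("rt_trials must be 'correct' or 'all'")
    df = trials if include_block_start else trials[~trials["block_start"]]
    df = df.copy()
    resolved = df["rt"].notna()
    use_rt = resolved & (df["correct"] if rt_trials == "correct" else True)
    df["_rt_use"] = df["rt"].where(use_rt)
    keys = ["subject_id", "condition", "block_index", "block_phase",
            "trial_type"]
    out = df.groupby(keys, sort=True).agg(
        n_trials=("correct", "size"),
        n_resolved=("rt", "count"),
        accuracy=("correct", "mean"),
        mean_rt=("_rt_use", "mean"),
    ).reset_index()
    out["rt_missing"] = out["mean_rt"].isna()
    return out


@dataclass
class SwitchCostTable:
    """Ratio switch costs per subject x block plus change scores.

    ``per_block`` : switch and non-switch cell means with their ratios.
    ``training_change`` : per subject, first-minus-last training block
    change in RT and accuracy switch cost (positive = cost shrank).
    ``prepost_change`` : the same contrast between matched pre and post
    blocks, separately for familiar and novel stimulus sets (the first
    and last of the four pre/post blocks use novel stimuli).
    """

    per_block: pd.DataFrame
    training_change: pd.DataFrame
    prepost_change: pd.DataFrame
    method: str = "ratio"


def _cost(numer, denom, method):
    if method == "ratio":
        out = numer / denom
        out[(denom <= 0) | numer.isna()] = np.nan
        return out
    return numer - denom


def switch_cost(summary: pd.DataFrame, method: str = "ratio") -> SwitchCostTable:
    """Build the switch-cost table from :func:`block_summaries` output.

    ``method="ratio"`` divides switch by non-switch performance (the
    primary definition; it scales out baseline differences);
    ``"difference"`` subtracts instead.  Change scores subtract the last
    training block from the first.  Cells with a missing or zero
    denominator yield missing costs with a reason column."""
    if method not in ("ratio", "difference"):
        raise ValueError("method must be 'ratio' or 'difference'")
    wide = summary.pivot_table(
        index=["subject_id", "condition", "block_index", "block_phase"],
        columns="trial_type", values=["mean_rt", "accuracy"],
        aggfunc="first").reset_index()
    wide.columns = ["_".join(c).rstrip("_") if c[1] else c[0]
                    for c in wide.columns]
    for col in ("mean_rt_switch", "mean_rt_nonswitch",
                "accuracy_switch", "accuracy_nonswitch"):
        if col not in wide:
            wide[col] = np.nan
    per = wide.rename(columns={
        "mean_rt_switch": "rt_switch", "mean_rt_nonswitch": "rt_nonswitch",
        "accuracy_switch": "acc_switch", "accuracy_nonswitch": "acc_nonswitch"})
    per["rt_cost"] = _cost(per["rt_switch"], per["rt_nonswitch"], method)
    per["acc_cost"] = _cost(per["acc_switch"], per["acc_nonswitch"], method)
    per["missing_reason"] = np.where(
        per["rt_cost"].notna(), "",
        np.where(per["rt_nonswitch"].isna(), "missing non-switch cell",
                 np.where(per["rt_switch"].isna(), "missing switch cell",
                          "zero denominator")))

    training = per[per["block_phase"] == "training"]
    rows = []
    if len(training):
        b_first = training["block_index"].min()
        b_last = training["block_index"].max()
        for (sid, cond), sub in training.groupby(["subject_id", "condition"]):
            first = sub[sub["block_index"] == b_first]
            last = sub[sub["block_index"] == b_last]
            row = {"subject_id": sid, "condition": cond,
                   "block_first": b_first, "block_last": b_last,
                   "rt_cost_change": np.nan, "acc_cost_change": np.nan}
            if len(first) and len(last):
                row["rt_cost_change"] = (first["rt_cost"].iloc[0]
                                         - last["rt_cost"].iloc[0])
                row["acc_cost_change"] = (first["acc_cost"].iloc[0]
                                          - last["acc_cost"].iloc[0])
            rows.append(row)
    training_change = pd.DataFrame(rows)

    # pre/post transfer: of the four pre/post blocks the outermost pair
    # (first pre, last post) uses novel stimuli, the innermost pair the
    # familiar training stimuli
    pp_rows = []
    pre = per[per["block_phase"] == "pre"]
    post = per[per["block_phase"] == "post"]
    if len(pre) and len(post):
        pre_blocks = sorted(pre["block_index"].unique())
        post_blocks = sorted(post["block_index"].unique())
        pairs = {"novel": (pre_blocks[0], post_blocks[-1]),
                 "familiar": (pre_blocks[-1], post_blocks[0])}
        if len(pre_blocks) < 2 or len(post_blocks) < 2:
            pairs = {"novel": (pre_blocks[0], post_blocks[-1])}
        for stim, (bp, bq) in pairs.items():
            sub_pre = per[per["block_index"] == bp].set_index("subject_id")
            sub_post = per[per["block_index"] == bq].set_index("subject_id")
            common = sub_pre.index.intersection(sub_post.index)
            for sid in common:
                pp_rows.append({
                    "subject_id": sid,
                    "condition": sub_pre.loc[sid, "condition"],
                    "stimulus_set": stim,
                    "pre_block": bp, "post_block": bq,
                    "rt_cost_change": sub_pre.loc[sid, "rt_cost"]
                    - sub_post.loc[sid, "rt_cost"],
                    "acc_cost_change": sub_pre.loc[sid, "acc_cost"]
                    - sub_post.loc[sid, "acc_cost"]})
    prepost_change = pd.DataFrame(pp_rows)
    return SwitchCostTable(per_block=per.reset_index(drop=True),
                           training_change=training_change,
                           prepost_change=prepost_change, method=method)


# ---------------------------------------------------------------------------
# mixed ANOVA

def mixed_anova(data: pd.DataFrame, dv: str, within: list[str],
                between: str, subject: str = "subject_id") -> pd.DataFrame:
    """Univariate mixed-design (split-plot) ANOVA with one
    between-subject factor and one or two within-subject factors,
    subjects treated as random.

    Expects one value per subject x within-cell (aggregate first).  Each
    within-subject effect is tested against its interaction with
    subjects nested in groups; the between effect against subjects
    within groups.  Group sizes may differ (marginal means are then
    subject-weighted); subjects with incomplete within-cells are dropped
    and reported via the ``incomplete_subjects`` frame attribute.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports one or two within factors")
    df = data[[subject, between, dv] + within].dropna(subset=[dv]).copy()
    piv = df.pivot_table(index=[subject, between], columns=within, values=dv,
                         aggfunc="mean")
    complete = piv.dropna()
    incomplete = sorted(piv.index.get_level_values(0)[piv.isna().any(axis=1)])
    if complete.index.get_level_values(1).nunique() < 2:
        raise ValueError("need >= 2 levels of the between factor")
    N = len(complete)
    if N < 2:
        raise ValueError("need >= 2 complete subjects")
    if len(within) == 2:
        b_levels = piv.columns.get_level_values(0).nunique()
        w_levels = piv.columns.get_level_values(1).nunique()
    else:
        b_levels = piv.columns.nunique()
        w_levels = 1
    Y = complete.to_numpy().reshape(N, b_levels, w_levels)
    grp_labels, grp = np.unique(
        complete.index.get_level_values(1), return_inverse=True)
    g = len(grp_labels)
    n_g = np.bincount(grp)

    grand = Y.mean()
    s_mean = Y.mean(axis=(1, 2))
    g_mean = np.array([s_mean[grp == i].mean() for i in range(g)])
    b_mean = Y.mean(axis=(0, 2))
    gb_mean = np.stack([Y[grp == i].mean(axis=(0, 2)) for i in range(g)])
    sb_mean = Y.mean(axis=2)

    B, W = b_levels, w_levels
    ss_G = B * W * float((n_g * (g_mean - grand) ** 2).sum())
    ss_S = B * W * float(((s_mean - g_mean[grp]) ** 2).sum())
    df_G, df_S = g - 1, N - g
    ss_B = W * N * float(((b_mean - grand) ** 2).sum())
    ss_GB = W * float((n_g[:, None] * (gb_mean - g_mean[:, None]
                                       - b_mean[None, :] + grand) ** 2).sum())
    ss_SB = W * float(((sb_mean - s_mean[:, None] - gb_mean[grp]
                        + g_mean[grp, None]) ** 2).sum())
    rows = [
        {"effect": between, "ss": ss_G, "df1": df_G,
         "ss_err": ss_S, "df2": df_S},
        {"effect": within[0], "ss": ss_B, "df1": B - 1,
         "ss_err": ss_SB, "df2": (B - 1) * df_S},
        {"effect": f"{within[0]} x {between}", "ss": ss_GB,
         "df1": (B - 1) * df_G, "ss_err": ss_SB, "df2": (B - 1) * df_S},
    ]
    if W > 1:
        w_mean = Y.mean(axis=(0, 1))
        gw_mean = np.stack([Y[grp == i].mean(axis=(0, 1)) for i in range(g)])
        sw_mean = Y.mean(axis=1)
        bw_mean = Y.mean(axis=0)
        gbw_mean = np.stack([Y[grp == i].mean(axis=0) for i in range(g)])
        ss_W = B * N * float(((w_mean - grand) ** 2).sum())
        ss_GW = B * float((n_g[:, None] * (gw_mean - g_mean[:, None]
                                           - w_mean[None, :] + grand) ** 2).sum())
        ss_SW = B * float(((sw_mean - s_mean[:, None] - gw_mean[grp]
                            + g_mean[grp, None]) ** 2).sum())
        ss_BW = N * float(((bw_mean - b_mean[:, None] - w_mean[None, :]
                            + grand) ** 2).sum())
        ss_GBW = float((n_g[:, None, None] * (
            gbw_mean - gb_mean[:, :, None] - gw_mean[:, None, :]
            - bw_mean[None] + g_mean[:, None, None]
            + b_mean[None, :, None] + w_mean[None, None, :] - grand) ** 2).sum())
        ss_SBW = float(((Y - sb_mean[:, :, None] - sw_mean[:, None, :]
                         - gbw_mean[grp] + s_mean[:, None, None]
                         + gb_mean[grp][:, :, None] + gw_mean[grp][:, None, :]
                         - g_mean[grp][:, None, None]) ** 2).sum())
        df_SW = (W - 1) * df_S
        df_SBW = (B - 1) * (W - 1) * df_S
        rows += [
            {"effect": within[1], "ss": ss_W, "df1": W - 1,
             "ss_err": ss_SW, "df2": df_SW},
            {"effect": f"{within[1]} x {between}", "ss": ss_GW,
             "df1": (W - 1) * df_G, "ss_err": ss_SW, "df2": df_SW},
            {"effect": f"{within[0]} x {within[1]}", "ss": ss_BW,
             "df1": (B - 1) * (W - 1), "ss_err": ss_SBW, "df2": df_SBW},
            {"effect": f"{within[0]} x {within[1]} x {between}",
             "ss": ss_GBW, "df1": (B - 1) * (W - 1) * df_G,
             "ss_err": ss_SBW, "df2": df_SBW},
        ]
    out = pd.DataFrame(rows)
    out["ms"] = out["ss"] / out["df1"]
    out["ms_err"] = out["ss_err"] / out["df2"]
    out["F"] = out["ms"] / out["ms_err"]
    out["p"] = stats.f.sf(out["F"], out["df1"], out["df2"])
    out["eta_p2"] = out["ss"] / (out["ss"] + out["ss_err"])
    out.attrs["incomplete_subjects"] = incomplete
    return out


@dataclass
class ConditionContrasts:
    """The study's contrast structure on a cohort."""

    rt_anova: pd.DataFrame
    accuracy_anova: pd.DataFrame
    block_endpoint_ttests: pd.DataFrame
    cost_change_oneway: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rt_anova": self.rt_anova.to_dict(orient="records"),
            "accuracy_anova": self.accuracy_anova.to_dict(orient="records"),
            "block_endpoint_ttests":
                self.block_endpoint_ttests.to_dict(orient="records"),
            "cost_change_oneway":
                self.cost_change_oneway.to_dict(orient="records"),
            "flags": self.flags,
        }


def condition_contrasts(trials: pd.DataFrame,
                        summary: pd.DataFrame | None = None,
                        cost: SwitchCostTable | None = None,
                        alpha: float = 0.05) -> ConditionContrasts:
    """Main effects and interactions of Block, Trial Type and feedback
    Condition on training RT and accuracy (mixed ANOVA, subjects
    random), per-condition paired comparisons of the first and last
    training block, and a one-way comparison of switch-cost change
    across conditions."""
    if summary is None:
        summary = block_summaries(trials)
    if cost is None:
        cost = switch_cost(summary)
    train = summary[summary["block_phase"] == "training"].copy()
    if train["condition"].nunique() < 2:
        raise ValueError("need >= 2 feedback conditions")
    if train["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    flags = {}
    rt_anova = mixed_anova(train.dropna(subset=["mean_rt"]), "mean_rt",
                           ["block_index", "trial_type"], "condition")
    acc_anova = mixed_anova(train, "accuracy",
                            ["block_index", "trial_type"], "condition")
    for name, table in (("rt", rt_anova), ("accuracy", acc_anova)):
        if table.attrs.get("incomplete_subjects"):
            flags[f"{name}_incomplete_subjects"] = \
                table.attrs["incomplete_subjects"]

    b_first = int(train["block_index"].min())
    b_last = int(train["block_index"].max())
    t_rows = []
    for cond, sub in train.groupby("condition"):
        piv = sub.groupby(["subject_id", "block_index"])["mean_rt"].mean() \
            .unstack("block_index")
        acc_piv = sub.groupby(["subject_id", "block_index"])["accuracy"] \
            .mean().unstack("block_index")
        for dv, tab in (("mean_rt", piv), ("accuracy", acc_piv)):
            if b_first in tab and b_last in tab:
                pair = tab[[b_first, b_last]].dropna()
                if len(pair) >= 2:
                    t, pval = stats.ttest_rel(pair[b_first], pair[b_last])
                    d = ((pair[b_first] - pair[b_last]).mean()
                         / max(float((pair[b_first] - pair[b_last]).std(ddof=1)),
                               1e-12))
                    t_rows.append({"condition": cond, "dv": dv,
                                   "block_first": b_first,
                                   "block_last": b_last,
                                   "n": len(pair), "t": float(t),
                                   "p": float(pval), "cohen_d": float(d),
                                   "significant": bool(pval < alpha)})
    ttests = pd.DataFrame(t_rows)

    ow_rows = []
    for dv in ("rt_cost_change", "acc_cost_change"):
        groups = [g[dv].dropna().to_numpy()
                  for _, g in cost.training_change.groupby("condition")]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            F, pval = stats.f_oneway(*groups)
            ow_rows.append({"dv": dv, "F": float(F), "p": float(pval),
                            "significant": bool(pval < alpha)})
    oneway = pd.DataFrame(ow_rows)
    return ConditionContrasts(rt_anova=rt_anova, accuracy_anova=acc_anova,
                              block_endpoint_ttests=ttests,
                              cost_change_oneway=oneway, flags=flags)


def within_subject_se(data: pd.DataFrame, dv: str, within: list[str],
                      subject: str = "subject_id") -> pd.DataFrame:
    """Within-subject standard errors per within-cell
    (Cousineau normalisation with the Morey correction).

    Each observation is recentred by its subject's mean toward the grand
    mean, removing between-subject offsets; cell SEs of the recentred
    values are then inflated by sqrt(C / (C - 1)) for the C within
    cells.  Suitable for error bars on repeated-measures condition
    means."""
    df = data[[subject, dv] + within].dropna(subset=[dv]).copy()
    grand = df[dv].mean()
    subj_mean = df.groupby(subject, observed=True)[dv].transform("mean")
    df["_norm"] = df[dv] - subj_mean + grand
    n_cells = int(df.groupby(within, observed=True).ngroups)
    correction = np.sqrt(n_cells / max(n_cells - 1, 1))
    out = df.groupby(within, observed=True).agg(
        mean=(dv, "mean"), n=("_norm", "size"), sd_norm=("_norm", "std"))
    out["se_within"] = correction * out["sd_norm"] / np.sqrt(out["n"])
    return out.drop(columns=["sd_norm"]).reset_index()


# ---------------------------------------------------------------------------
# diffusion-parameter trajectories

def parameter_trajectories(param_table: pd.DataFrame) -> dict:
    """Switch costs of fitted diffusion parameters and their
    first-to-last block changes.

    ``param_table`` is tidy with columns [block, trial_type, v, a] plus
    an optional subject_id (subject-level fits enable the paired
    boundary-vs-drift comparison).  The parameter switch cost in a block
    is the switch / non-switch ratio of that parameter; change scores
    subtract the last block from the first.  Missing endpoint blocks are
    flagged.
    """
    df = param_table.copy()
    block_col = "block" if "block" in df.columns else "block_index"
    has_subject = "subject_id" in df.columns and df["subject_id"].nunique() > 1
    group_keys = (["subject_id"] if "subject_id" in df.columns else [])
    wide = df.pivot_table(index=group_keys + [block_col],
                          columns="trial_type", values=["v", "a"],
                          aggfunc="first").reset_index()
    wide.columns = ["_".join(map(str, c)).rstrip("_") if c[1] else c[0]
                    for c in wide.columns]
    for col in ("v_switch", "v_nonswitch", "a_switch", "a_nonswitch"):
        if col not in wide:
            wide[col] = np.nan
    wide["v_cost"] = wide["v_switch"] / wide["v_nonswitch"]
    wide["a_cost"] = wide["a_switch"] / wide["a_nonswitch"]
    blocks = sorted(df[block_col].unique())
    b_first, b_last = blocks[0], blocks[-1]
    missing = []

    def endpoint_change(sub):
        first = sub[sub[block_col] == b_first]
        last = sub[sub[block_col] == b_last]
        if not len(first) or not len(last):
            return None
        out = {"v_cost_change": float(first["v_cost"].iloc[0]
                                      - last["v_cost"].iloc[0]),
               "a_cost_change": float(first["a_cost"].iloc[0]
                                      - last["a_cost"].iloc[0])}
        # raw first-minus-last parameter changes per trial type, kept
        # alongside the ratio costs (the two orderings can differ)
        for col in ("v_switch", "v_nonswitch", "a_switch", "a_nonswitch"):
            out[f"{col}_change"] = float(first[col].iloc[0]
                                         - last[col].iloc[0])
        return out

    changes = []
    if group_keys:
        for sid, sub in wide.groupby("subject_id"):
            ch = endpoint_change(sub)
            if ch is None:
                missing.append(sid)
            else:
                changes.append({"subject_id": sid, **ch})
    else:
        ch = endpoint_change(wide)
        if ch is None:
            missing.append("(pooled)")
        else:
            changes.append(ch)
    change_df = pd.DataFrame(changes)
    out = {"per_block": wide, "change": change_df,
           "block_first": b_first, "block_last": b_last,
           "missing_endpoints": missing}
    if len(change_df):
        a_ch = change_df["a_cost_change"].mean()
        v_ch = change_df["v_cost_change"].mean()
        out["boundary_change_exceeds_drift_change"] = bool(a_ch > v_ch)
        a_raw = change_df[["a_switch_change", "a_nonswitch_change"]] \
            .abs().to_numpy().mean()
        v_raw = change_df[["v_switch_change", "v_nonswitch_change"]] \
            .abs().to_numpy().mean()
        out["boundary_raw_change_exceeds_drift_raw_change"] = \
            bool(a_raw > v_raw)
        if has_subject and len(change_df) >= 2:
            t, pval = stats.ttest_rel(change_df["a_cost_change"],
                                      change_df["v_cost_change"])
            out["paired_t"] = {"t": float(t), "p": float(pval),
                               "n": int(len(change_df))}
    return out
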