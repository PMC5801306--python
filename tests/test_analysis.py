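"""Behavioural pipeline: exclusion, block summaries, switch costs,
condition contrasts and diffusion-parameter trajectories."""

import numpy as np
import pandas as pd
import pytest

import switchddm as sw
from switchddm.analysis import (
    block_summaries,
    condition_contrasts,
    exclude_participants,
    mixed_anova,
    parameter_trajectories,
    switch_cost,
    within_subject_se,
)


def _table(rows):
    """Trial table from (subject, block, phase, trial_type, correct, rt)."""
    df = pd.DataFrame(rows, columns=["subject_id", "block_index",
                                     "block_phase", "trial_type", "correct",
                                     "rt"])
    df["condition"] = "NFB"
    df["trial_index"] = df.groupby(["subject_id", "block_index"]).cumcount() + 2
    df["block_start"] = False
    df["coins"] = 0
    df["iti"] = 0.7
    df["lapse_flag"] = False
    return df


class TestExclusion:
    def test_low_accuracy_subjects_listed(self):
        rows = []
        for sid, acc in [("good", 0.95), ("bad1", 0.70), ("bad2", 0.60),
                         ("bad3", 0.79), ("edge", 0.80)]:
            for i in range(100):
                rows.append((sid, 3, "training", "nonswitch",
                             i < int(acc * 100), 0.5))
        trials = _table(rows)
        kept, report = exclude_participants(trials, threshold=0.80)
        assert sorted(report["subject_id"]) == ["bad1", "bad2", "bad3"]
        assert set(kept["subject_id"]) == {"good", "edge"}
        assert report["accuracy"].between(0, 0.8, inclusive="left").all()

    def test_perfect_cohort_keeps_everyone(self):
        trials = _table([(f"s{i}", 3, "training", "nonswitch", True, 0.5)
                         for i in range(4) for _ in range(20)])
        kept, report = exclude_participants(trials)
        assert len(report) == 0
        assert kept["subject_id"].nunique() == 4

    def test_idempotent(self):
        rows = [("a", 3, "training", "nonswitch", i % 2 == 0, 0.5)
                for i in range(50)]
        rows += [("b", 3, "training", "nonswitch", True, 0.5)
                 for _ in range(50)]
        trials = _table(rows)
        once, _ = exclude_participants(trials)
        twice, rep2 = exclude_participants(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(rep2) == 0

    def test_only_training_blocks_count(self):
        rows = [("s", 1, "pre", "nonswitch", False, 0.5)
                for _ in range(100)]
        rows += [("s", 3, "training", "nonswitch", True, 0.5)
                 for _ in range(100)]
        kept, report = exclude_participants(_table(rows))
        assert len(report) == 0

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            exclude_participants(_table([]).iloc[:0])
        with pytest.raises(ValueError):
            exclude_participants(
                _table([("s", 3, "training", "nonswitch", True, 0.5)]),
                threshold=1.2)

    def test_generative_low_accuracy_subject_is_excluded(self):
        # accuracy ~ (1 - 0.1) * logistic(0.9 * 1.1) + 0.05 ~ 0.70
        weak = sw.simulate_trials(sw.DDMParams(0.9, 1.1, 0.3, 0.10),
                                  400, seed=8)
        weak["subject_id"] = "weak"
        strong = sw.simulate_trials(sw.DDMParams(2.6, 2.0, 0.3, 0.10),
                                    400, seed=9)
        strong["subject_id"] = "strong"
        trials = pd.concat([weak, strong], ignore_index=True)
        _, report = exclude_participants(trials)
        assert list(report["subject_id"]) == ["weak"]


class TestBlockSummaries:
    def test_mean_rt_over_correct_trials(self):
        trials = _table([("s", 3, "training", "nonswitch", True, 0.4),
                         ("s", 3, "training", "nonswitch", True, 0.6),
                         ("s", 3, "training", "nonswitch", False, 1.9)])
        out = block_summaries(trials)
        assert out["mean_rt"].iloc[0] == pytest.approx(0.5)
        assert out["accuracy"].iloc[0] == pytest.approx(2 / 3)
        out_all = block_summaries(trials, rt_trials="all")
        assert out_all["mean_rt"].iloc[0] == pytest.approx((0.4 + 0.6 + 1.9) / 3)

    def test_all_omission_cell_flagged(self):
        trials = _table([("s", 3, "training", "switch", False, np.nan),
                         ("s", 3, "training", "switch", False, np.nan)])
        out = block_summaries(trials)
        assert out["rt_missing"].iloc[0]
        assert np.isnan(out["mean_rt"].iloc[0])
        assert out["accuracy"].iloc[0] == 0.0

    def test_block_start_excluded_by_default(self):
        trials = _table([("s", 3, "training", "nonswitch", True, 0.4),
                         ("s", 3, "training", "nonswitch", True, 0.8)])
        trials.loc[trials.index[0], "block_start"] = True
        assert block_summaries(trials)["mean_rt"].iloc[0] == pytest.approx(0.8)
        both = block_summaries(trials, include_block_start=True)
        assert both["mean_rt"].iloc[0] == pytest.approx(0.6)

    def test_cell_accuracy_matches_closed_form(self):
        p = sw.DDMParams(2.0, 2.0, 0.3, 0.10)
        trials = sw.simulate_trials(p, 20_000, deadline=6.0, seed=14)
        out = block_summaries(trials)
        expected = sw.observed_accuracy(p)
        se = np.sqrt(expected * (1 - expected) / len(trials))
        assert out["accuracy"].iloc[0] == pytest.approx(expected, abs=3 * se)


class TestSwitchCost:
    def _summary(self, cells):
        rows = []
        for sid, blk, tt, rt, acc in cells:
            rows.append({"subject_id": sid, "condition": "NFB",
                         "block_index": blk, "block_phase": "training",
                         "trial_type": tt, "n_trials": 10, "n_resolved": 10,
                         "accuracy": acc, "mean_rt": rt, "rt_missing": False})
        return pd.DataFrame(rows)

    def test_ratio_definition(self):
        summ = self._summary([("s", 1, "switch", 0.600, 0.90),
                              ("s", 1, "nonswitch", 0.500, 0.95)])
        cost = switch_cost(summ)
        assert cost.per_block["rt_cost"].iloc[0] == pytest.approx(1.2)
        assert cost.per_block["acc_cost"].iloc[0] == pytest.approx(0.90 / 0.95)

    def test_identical_cells_and_change_zero(self):
        summ = self._summary([(s, b, tt, 0.5, 0.9)
                              for s in ["s"] for b in [1, 10]
                              for tt in ["switch", "nonswitch"]])
        cost = switch_cost(summ)
        assert (cost.per_block["rt_cost"] == 1.0).all()
        assert cost.training_change["rt_cost_change"].iloc[0] == 0.0

    def test_missing_denominator_reported(self):
        summ = self._summary([("s", 1, "switch", 0.6, 0.9)])
        cost = switch_cost(summ)
        assert np.isnan(cost.per_block["rt_cost"].iloc[0])
        assert "non-switch" in cost.per_block["missing_reason"].iloc[0]

    def test_difference_variant(self):
        summ = self._summary([("s", 1, "switch", 0.600, 0.90),
                              ("s", 1, "nonswitch", 0.500, 0.95)])
        cost = switch_cost(summ, method="difference")
        assert cost.per_block["rt_cost"].iloc[0] == pytest.approx(0.1)

    def test_boundary_decline_produces_positive_rt_cost_change(self):
        """If only the switch-trial boundary drops across training, RT
        switch cost falls from first to last block (positive change)."""
        cfg = sw.SessionConfig(n_pre_blocks=1, n_training_blocks=2,
                               n_post_blocks=1, trials_per_block=120)
        cells = {}
        for b in range(1, cfg.n_blocks + 1):
            a_sw = 3.2 if b <= 2 else 2.3
            cells[("switch", b)] = sw.DDMParams(2.6, a_sw, 0.3, 0.10)
            cells[("nonswitch", b)] = sw.DDMParams(2.6, 2.0, 0.3, 0.10)
        grid = sw.GenerativeGrid(cells)
        st_df = sw.build_session_structure(cfg)
        frames = [sw.simulate_session(st_df, grid, f"s{i}", 100 + i,
                                      config=cfg) for i in range(10)]
        cost = switch_cost(block_summaries(pd.concat(frames)))
        assert cost.training_change["rt_cost_change"].mean() > 0

    def test_prepost_novel_and_familiar_pairs(self, two_condition_cohort):
        # cohort has no pre/post rows: change table is empty but valid
        cost = switch_cost(block_summaries(two_condition_cohort))
        assert len(cost.prepost_change) == 0
        # with pre/post blocks present both stimulus sets appear
        cfg = sw.SessionConfig(n_pre_blocks=2, n_training_blocks=1,
                               n_post_blocks=2, trials_per_block=40)
        grid = sw.GenerativeGrid.constant(sw.DDMParams(2.5, 2.0), cfg)
        st_df = sw.build_session_structure(cfg)
        ses = sw.simulate_session(st_df, grid, "s", 3, config=cfg)
        pp = switch_cost(block_summaries(ses)).prepost_change
        assert set(pp["stimulus_set"]) == {"novel", "familiar"}
        novel = pp[pp["stimulus_set"] == "novel"].iloc[0]
        assert (novel["pre_block"], novel["post_block"]) == (1, 5)


class TestMixedAnova:
    @staticmethod
    def _toy(seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(14):
            grp = "A" if i < 7 else "B"
            base = rng.normal(0, 0.5)
            for blk in (1, 2, 3):
                rows.append({"subject_id": f"s{i}", "condition": grp,
                             "block_index": blk,
                             "y": base + rng.normal(0, 0.3)
                             + (effect if grp == "B" else 0.0)})
        return pd.DataFrame(rows)

    def test_matches_pingouin_one_within(self):
        pingouin = pytest.importorskip("pingouin")
        df = self._toy(seed=3, effect=0.4)
        mine = mixed_anova(df, "y", ["block_index"], "condition")
        theirs = pingouin.mixed_anova(df, dv="y", within="block_index",
                                      subject="subject_id",
                                      between="condition")
        pairs = {"condition": "condition", "block_index": "block_index",
                 "block_index x condition": "Interaction"}
        for my_name, pg_name in pairs.items():
            mine_row = mine[mine["effect"] == my_name].iloc[0]
            pg_row = theirs[theirs["Source"] == pg_name].iloc[0]
            assert mine_row["F"] == pytest.approx(pg_row["F"], rel=1e-6)
            assert mine_row["p"] == pytest.approx(pg_row["p_unc"], rel=1e-6)

    def test_incomplete_subjects_flagged(self):
        df = self._toy()
        df = df[~((df["subject_id"] == "s0") & (df["block_index"] == 3))]
        out = mixed_anova(df, "y", ["block_index"], "condition")
        assert out.attrs["incomplete_subjects"] == ["s0"]


class TestConditionContrasts:
    def test_preconditions(self, two_condition_cohort):
        single_subj = two_condition_cohort[
            two_condition_cohort["subject_id"] == "s00"]
        with pytest.raises(ValueError):
            condition_contrasts(single_subj)
        single_cond = two_condition_cohort[
            two_condition_cohort["condition"] == "NFB"]
        with pytest.raises(ValueError):
            condition_contrasts(single_cond)

    def test_null_cohort_structure(self, two_condition_cohort):
        out = condition_contrasts(two_condition_cohort)
        effects = set(out.rt_anova["effect"])
        assert {"condition", "block_index", "trial_type",
                "block_index x trial_type",
                "block_index x trial_type x condition"} <= effects
        assert len(out.block_endpoint_ttests) == 4  # 2 conditions x 2 dvs
        assert set(out.cost_change_oneway["dv"]) == {"rt_cost_change",
                                                     "acc_cost_change"}

    def test_boundary_difference_between_conditions_is_detected(self):
        """Conditions generated with distinct switch-trial boundaries
        separate on RT with high power."""
        cfg = sw.SessionConfig(n_pre_blocks=1, n_training_blocks=3,
                               n_post_blocks=1, trials_per_block=60)
        st_df = sw.build_session_structure(cfg)
        st_df = st_df[st_df["block_phase"] == "training"].reset_index(drop=True)
        frames = []
        for c_idx, (cond, a_sw) in enumerate([("NFB", 3.2), ("MFB", 2.2)]):
            cells = {}
            for b in range(2, 5):
                cells[("switch", b)] = sw.DDMParams(2.6, a_sw, 0.3, 0.10)
                cells[("nonswitch", b)] = sw.DDMParams(2.6, 2.0, 0.3, 0.10)
            grid = sw.GenerativeGrid(cells, {"v": 0.2, "a": 0.2, "t0": 0.03})
            cfg_c = sw.SessionConfig(**{**cfg.__dict__, "condition": cond,
                                        "coin_value_cents": None})
            for i, ss in enumerate(
                    np.random.SeedSequence([77, c_idx]).spawn(10)):
                rng = np.random.default_rng(ss)
                frames.append(sw.simulate_session(
                    st_df, grid.draw_subject(rng), f"{cond}{i}", rng,
                    config=cfg_c))
        out = condition_contrasts(pd.concat(frames, ignore_index=True))
        p_cond = float(out.rt_anova.loc[out.rt_anova["effect"] == "condition",
                                        "p"].iloc[0])
        assert p_cond < 0.01


class TestWithinSubjectSE:
    def test_removes_between_subject_offsets(self):
        """Large subject offsets do not inflate the within-subject SE:
        with identical condition effects across subjects the normalised
        SE is (up to the Morey factor) zero."""
        rows = []
        for i, offset in enumerate([0.0, 5.0, -3.0, 10.0]):
            for cond, effect in (("x", 0.0), ("y", 0.2)):
                rows.append({"subject_id": f"s{i}", "cond": cond,
                             "y": offset + effect})
        df = pd.DataFrame(rows)
        out = within_subject_se(df, "y", ["cond"])
        assert np.allclose(out["se_within"], 0.0, atol=1e-12)
        naive_sd = df[df["cond"] == "x"]["y"].std()
        assert naive_sd > 1  # the raw spread the normalisation removed

    def test_matches_manual_computation(self):
        rng = np.random.default_rng(5)
        rows = [{"subject_id": f"s{i}", "cond": c,
                 "y": rng.normal(i, 1.0) + (0.3 if c == "y" else 0)}
                for i in range(6) for c in ("x", "y")]
        df = pd.DataFrame(rows)
        out = within_subject_se(df, "y", ["cond"]).set_index("cond")
        norm = df["y"] - df.groupby("subject_id")["y"].transform("mean") \
            + df["y"].mean()
        manual = norm[df["cond"] == "x"].std() / np.sqrt(6) * np.sqrt(2)
        assert out.loc["x", "se_within"] == pytest.approx(manual)


class TestParameterTrajectories:
    def test_boundary_only_change(self):
        tab = pd.DataFrame([
            {"block": 1, "trial_type": "switch", "v": 2.6, "a": 3.2},
            {"block": 1, "trial_type": "nonswitch", "v": 2.6, "a": 2.0},
            {"block": 10, "trial_type": "switch", "v": 2.6, "a": 2.4},
            {"block": 10, "trial_type": "nonswitch", "v": 2.6, "a": 2.0},
        ])
        out = parameter_trajectories(tab)
        ch = out["change"].iloc[0]
        assert ch["v_cost_change"] == pytest.approx(0.0)
        assert ch["a_cost_change"] == pytest.approx(3.2 / 2.0 - 2.4 / 2.0)
        assert out["boundary_change_exceeds_drift_change"]

    def test_identical_fits_give_zero_change(self):
        tab = pd.DataFrame([
            {"block": b, "trial_type": tt, "v": 2.5, "a": 2.2}
            for b in (1, 10) for tt in ("switch", "nonswitch")])
        out = parameter_trajectories(tab)
        assert out["change"].iloc[0]["v_cost_change"] == 0.0
        assert out["change"].iloc[0]["a_cost_change"] == 0.0

    def test_missing_endpoint_flagged(self):
        tab = pd.DataFrame([
            {"subject_id": "s1", "block": 1, "trial_type": "switch",
             "v": 2.5, "a": 2.2},
            {"subject_id": "s1", "block": 1, "trial_type": "nonswitch",
             "v": 2.5, "a": 2.0},
        ])
        tab2 = tab.copy()
        tab2["block"] = 10
        tab2["subject_id"] = "s2"
        out = parameter_trajectories(pd.concat([tab, tab2]))
        assert set(out["missing_endpoints"]) == {"s1", "s2"}
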