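"""Session generator: block/switch schedule, diffusion-driven trial
outcomes, feedback-coin rules and cohort assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

import switchddm as sw
from switchddm.config import ConfigError
from switchddm.taskgen import bfb_block_summary, score_coins


class TestSessionStructure:
    def test_default_design_has_840_trials(self):
        st_df = sw.build_session_structure()
        assert len(st_df) == 840
        assert st_df["block_index"].nunique() == 14

    def test_fifteen_switch_trials_per_default_block(self):
        st_df = sw.build_session_structure()
        per_block = st_df.groupby("block_index")["trial_type"] \
            .apply(lambda s: (s == "switch").sum())
        assert (per_block == 60 // 4).all()

    def test_minimal_block_has_one_switch(self):
        cfg = sw.SessionConfig(n_pre_blocks=1, n_training_blocks=1,
                               n_post_blocks=1, trials_per_block=4)
        st_df = sw.build_session_structure(cfg)
        assert (st_df.groupby("block_index")["trial_type"]
                .apply(lambda s: (s == "switch").sum()) == 1).all()

    def test_block_start_is_nonswitch_and_flagged(self):
        st_df = sw.build_session_structure()
        first = st_df[st_df["trial_index"] == 1]
        assert (first["trial_type"] == "nonswitch").all()
        assert first["block_start"].all()
        assert not st_df[st_df["trial_index"] != 1]["block_start"].any()

    def test_pure_function_of_config(self):
        cfg = sw.SessionConfig()
        assert_frame_equal(sw.build_session_structure(cfg),
                           sw.build_session_structure(cfg))

    @pytest.mark.parametrize("kw,fragment", [
        ({"trials_per_block": 60, "switch_period": 7}, "divisible"),
        ({"deadline": -1.0}, "deadline"),
        ({"iti_range": (0.9, 0.5)}, "iti_range"),
        ({"n_training_blocks": 0}, "n_training_blocks"),
        ({"condition": "XFB"}, "condition"),
    ])
    def test_invalid_config_names_violation(self, kw, fragment):
        with pytest.raises(ConfigError, match=fragment):
            sw.build_session_structure(sw.SessionConfig(**kw))


class TestSimulateSession:
    def test_pure_lapse_yields_coin_flip_accuracy(self, tiny_config):
        st_df = sw.build_session_structure(tiny_config)
        grid = sw.GenerativeGrid.constant(
            sw.DDMParams(2.58, 2.0, 0.3, lapse=1.0), tiny_config)
        ses = sw.simulate_session(st_df, grid, "s", 7, config=tiny_config)
        n = len(ses)
        assert ses["correct"].mean() == pytest.approx(
            0.5, abs=3 * math.sqrt(0.25 / n))
        assert ses["lapse_flag"].all()

    def test_accuracy_matches_logistic_identity(self):
        p = sw.DDMParams(2.58, 2.00, 0.3, lapse=0.0)
        trials = sw.simulate_trials(p, 20_000, deadline=10.0, seed=2)
        acc = trials["correct"].mean()
        expected = sw.choice_probability(p)  # 0.99429...
        se = math.sqrt(expected * (1 - expected) / len(trials))
        assert acc == pytest.approx(expected, abs=3 * se)

    def test_same_seed_identical_tables(self, tiny_config, endpoint_grid):
        st_df = sw.build_session_structure(tiny_config)
        a = sw.simulate_session(st_df, endpoint_grid, "s", 99, config=tiny_config)
        b = sw.simulate_session(st_df, endpoint_grid, "s", 99, config=tiny_config)
        assert_frame_equal(a, b)
        c = sw.simulate_session(st_df, endpoint_grid, "s", 100, config=tiny_config)
        assert not a["rt"].equals(c["rt"])

    def test_missing_grid_cell_is_named(self, tiny_config):
        st_df = sw.build_session_structure(tiny_config)
        grid = sw.GenerativeGrid({("switch", 1): sw.DDMParams(2.0, 2.0)})
        with pytest.raises(ConfigError, match=r"nonswitch.*1|missing grid cell"):
            sw.simulate_session(st_df, grid, "s", 1, config=tiny_config)

    def test_rt_within_deadline_or_missing(self, small_session, tiny_config):
        rt = small_session["rt"]
        ok = rt.isna() | ((rt > 0) & (rt <= tiny_config.deadline))
        assert ok.all()


def _trial(trial_type="nonswitch", correct=True, rt=0.5, phase="training"):
    return {"trial_type": trial_type, "correct": correct, "rt": rt,
            "block_phase": phase}


class TestFeedbackCoins:
    def test_nfb_always_zero(self):
        cfg = sw.SessionConfig(condition="NFB")
        assert sw.assign_feedback_coins(_trial(rt=0.3), cfg) == 0
        assert sw.assign_feedback_coins(_trial(correct=False), cfg) == 0

    def test_afb_marks_correctness_without_coins(self):
        cfg = sw.SessionConfig(condition="AFB")
        assert sw.assign_feedback_coins(_trial(), cfg) == 0

    def test_dfb_base_coin_outside_bonus_band(self):
        # 0.700 s > 0.600 * 1.05 = 0.630 s: base coin only
        cfg = sw.SessionConfig(condition="DFB")
        assert sw.assign_feedback_coins(_trial(rt=0.700), cfg) == 1

    def test_dfb_nonswitch_fast_bonus(self):
        cfg = sw.SessionConfig(condition="DFB")
        assert sw.assign_feedback_coins(_trial(rt=0.62), cfg) == 2

    def test_dfb_switch_bonus_tiers(self):
        cfg = sw.SessionConfig(condition="DFB")
        sw_trial = lambda rt: _trial("switch", rt=rt)
        assert sw.assign_feedback_coins(sw_trial(0.62), cfg) == 4   # 5% band
        assert sw.assign_feedback_coins(sw_trial(0.70), cfg) == 2   # 20% band
        assert sw.assign_feedback_coins(sw_trial(0.73), cfg) == 1   # outside

    def test_stacked_bonus_option(self):
        cfg = sw.SessionConfig(condition="DFB", stacked_bonus=True)
        assert sw.assign_feedback_coins(_trial("switch", rt=0.62), cfg) == 5

    def test_punishment_for_errors_and_omissions(self):
        for cond in ("PFB", "MFB", "BFB"):
            cfg = sw.SessionConfig(condition=cond)
            assert sw.assign_feedback_coins(_trial(correct=False), cfg) == -1
            assert sw.assign_feedback_coins(
                _trial(correct=True, rt=np.nan), cfg) == -1
        assert sw.assign_feedback_coins(
            _trial(correct=False), sw.SessionConfig(condition="DFB")) == 0

    def test_no_feedback_outside_training(self):
        cfg = sw.SessionConfig(condition="PFB")
        assert sw.assign_feedback_coins(_trial(phase="pre"), cfg) == 0

    def test_mfb_coin_value(self):
        assert sw.SessionConfig(condition="MFB").coin_value_cents == 0.2
        assert sw.SessionConfig(condition="PFB").coin_value_cents == 0.0

    def test_unknown_condition_rejected(self):
        cfg = sw.SessionConfig()
        object.__setattr__(cfg, "condition", "ZZZ")
        with pytest.raises(ConfigError):
            sw.assign_feedback_coins(_trial(), cfg)

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    def test_coins_nonincreasing_in_rt_for_correct_switch(self, rt1, rt2):
        cfg = sw.SessionConfig(condition="DFB")
        lo, hi = sorted([rt1, rt2])
        assert sw.assign_feedback_coins(_trial("switch", rt=lo), cfg) >= \
            sw.assign_feedback_coins(_trial("switch", rt=hi), cfg)

    def test_vectorised_scoring_matches_per_trial(self, small_session):
        cfg = sw.SessionConfig(condition="BFB")
        vec = score_coins(small_session, cfg)
        row_wise = [sw.assign_feedback_coins(row, cfg)
                    for _, row in small_session.iterrows()]
        np.testing.assert_array_equal(vec, row_wise)

    def test_bfb_block_summary(self, tiny_config, endpoint_grid):
        cfg = sw.SessionConfig(**{**tiny_config.__dict__,
                                  "condition": "BFB",
                                  "coin_value_cents": None})
        st_df = sw.build_session_structure(cfg)
        ses = sw.simulate_session(st_df, endpoint_grid, "s", 5, config=cfg)
        summ = bfb_block_summary(ses, cfg)
        assert set(summ["block_index"]) == {2, 3}  # training blocks only
        assert (summ["percent_of_total"] <= 100.0).all()
        manual = ses[(ses.block_index == 2)]["coins"].sum()
        assert summ.loc[summ.block_index == 2, "coins"].iloc[0] == manual


class TestCohort:
    def test_zero_dispersion_shares_parameters(self, endpoint_grid):
        rng = np.random.default_rng(0)
        drawn = endpoint_grid.draw_subject(rng)
        assert drawn.params == endpoint_grid.params

    def test_dispersion_spread_matches_sampler(self):
        grid = sw.GenerativeGrid(
            {("switch", 1): sw.DDMParams(2.5, 2.5, 0.3, 0.1)},
            {"v": 0.3, "a": 0.0, "t0": 0.0})
        rng = np.random.default_rng(12)
        vs = [grid.draw_subject(rng).params[("switch", 1)].v
              for _ in range(4000)]
        assert np.std(vs) == pytest.approx(0.3, abs=0.02)
        assert np.mean(vs) == pytest.approx(2.5, abs=0.02)

    def test_study_group_sizes_give_316_subjects(self):
        cfg = sw.SessionConfig(n_pre_blocks=1, n_training_blocks=1,
                               n_post_blocks=1, trials_per_block=4)
        grid = sw.GenerativeGrid.constant(sw.DDMParams(2.5, 2.0), cfg)
        cohort = sw.generate_cohort(grid=grid, seed=0, config=cfg)
        assert cohort["subject_id"].nunique() == 316
        sizes = cohort.groupby("condition")["subject_id"].nunique().to_dict()
        assert sizes == sw.STUDY_GROUP_SIZES

    def test_rejects_bad_group_sizes(self):
        with pytest.raises(ConfigError):
            sw.generate_cohort({"NFB": 0}, seed=0)
        with pytest.raises(ConfigError):
            sw.generate_cohort({"WAT": 3}, seed=0)

    def test_cohort_roundtrips_through_csv(self, tmp_path, tiny_config):
        grid = sw.GenerativeGrid.constant(sw.DDMParams(2.5, 2.0), tiny_config)
        cohort = sw.generate_cohort({"NFB": 2, "MFB": 1}, grid, seed=4,
                                    config=tiny_config)
        path = tmp_path / "cohort.csv"
        sw.write_trials(cohort, path)
        back = sw.read_trials(path, deadline=tiny_config.deadline)
        assert_frame_equal(back, cohort[sw.COLUMNS], check_dtype=False)
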