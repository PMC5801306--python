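"""Synthetic task-switching session generator.

Builds sessions with the study design (14 blocks x 60 trials, a task
switch every fourth trial, 2-s deadline), draws each trial's choice and
RT from the lapse-mixture diffusion for its (trial_type, block) cell, and
scores feedback coins under the six feedback schemes (NFB, AFB, DFB, PFB,
MFB, BFB).

Trial tables are tidy pandas DataFrames with one row per trial; see
:mod:`switchddm.io` for the on-disk schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CONDITIONS,
    STUDY_GROUP_SIZES,
    ConfigError,
    GenerativeGrid,
    SessionConfig,
)
from .ddm import DDMParams, sample_first_passage, simulate_walks

__all__ = [
    "build_session_structure",
    "simulate_session",
    "simulate_trials",
    "assign_feedback_coins",
    "score_coins",
    "bfb_block_summary",
    "generate_cohort",
]


def build_session_structure(config: SessionConfig | None = None) -> pd.DataFrame:
    """Ordered trial scaffold for one session.

    Switch trials fall on every ``switch_period``-th trial of a block
    (trial_index divisible by the period), giving
    ``trials_per_block / switch_period`` switch trials per block.  The
    first trial of each block has no within-block predecessor task; it is
    typed nonswitch and flagged ``block_start`` so the analysis can drop
    it from switch-cost cells.
    """
    config = (config or SessionConfig()).validate()
    rows = []
    for b in range(1, config.n_blocks + 1):
        phase = config.block_phase(b)
        for t in range(1, config.trials_per_block + 1):
            is_switch = t % config.switch_period == 0
            rows.append((b, phase, t,
                         "switch" if is_switch else "nonswitch", t == 1))
    return pd.DataFrame(rows, columns=["block_index", "block_phase",
                                       "trial_index", "trial_type",
                                       "block_start"])


def simulate_session(structure: pd.DataFrame, grid: GenerativeGrid,
                     subject_id: str, seed, config: SessionConfig | None = None,
                     method: str = "inverse_cdf", dt: float = 1e-4) -> pd.DataFrame:
    """Simulate one subject's session.

    Each trial's (correct, rt) is drawn from the lapse-mixture diffusion
    of its (trial_type, block) grid cell; walks that fail to resolve by
    the deadline are recorded as omissions (rt missing, scored
    incorrect).  ``method`` selects inverse-CDF sampling from the
    first-passage distribution (default, exact and fast) or the
    Euler-Maruyama forward walk (``"euler"``).  Identical seeds give
    identical tables.
    """
    config = (config or SessionConfig()).validate()
    grid.validate(structure)
    rng = np.random.default_rng(seed)
    n = len(structure)
    correct = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    lapse_flag = np.zeros(n, dtype=bool)
    cells = structure.groupby(["trial_type", "block_index"], sort=True).indices
    for (tt, blk), idx in sorted(cells.items()):
        p = grid.cell(tt, blk)
        m = len(idx)
        # draw the mixture indicator here so the table can carry the
        # generator-only ground-truth lapse flag
        is_lapse = rng.random(m) < p.lapse
        diffusion = DDMParams(p.v, p.a, p.t0, 0.0)
        ch = np.full(m, -1, dtype=np.int8)
        r = np.full(m, np.nan)
        n_diff = int((~is_lapse).sum())
        if n_diff:
            if method == "inverse_cdf":
                chd, rd = sample_first_passage(diffusion, n_diff,
                                               deadline=config.deadline, rng=rng)
            elif method == "euler":
                sub_seed = int(rng.integers(0, 2**31 - 1))
                chd, rd = simulate_walks(diffusion, n_diff, dt=dt,
                                         deadline=config.deadline, seed=sub_seed)
            else:
                raise ValueError(f"unknown simulation method {method!r}")
            ch[~is_lapse] = chd
            r[~is_lapse] = rd
        n_lapse = int(is_lapse.sum())
        if n_lapse:
            ch[is_lapse] = (rng.random(n_lapse) < 0.5).astype(np.int8)
            u = rng.random(n_lapse) * config.deadline
            r[is_lapse] = np.maximum(u, 1e-3)
        correct[idx] = ch == 1
        rt[idx] = r
        lapse_flag[idx] = is_lapse
    rt = np.round(rt, 3)
    rt[rt <= 0] = 0.001
    out = structure.copy()
    out.insert(0, "subject_id", str(subject_id))
    out.insert(1, "condition", config.condition)
    out["correct"] = correct
    out["rt"] = rt
    out["iti"] = np.round(rng.uniform(config.iti_range[0], config.iti_range[1], n), 3)
    out["lapse_flag"] = lapse_flag
    out["coins"] = score_coins(out, config)
    return out


def simulate_trials(params: DDMParams, n: int, deadline: float = 2.0,
                    seed=0, trial_type: str = "switch",
                    block_index: int = 1) -> pd.DataFrame:
    """Simulate ``n`` homogeneous trials of a single condition cell: the
    workhorse of parameter-recovery experiments.  Omissions are kept as
    rows with missing rt."""
    ch, rt = sample_first_passage(params, int(n), deadline=deadline, rng=seed)
    return pd.DataFrame({
        "subject_id": "s1",
        "condition": "NFB",
        "block_index": int(block_index),
        "block_phase": "training",
        "trial_index": np.arange(1, int(n) + 1),
        "trial_type": trial_type,
        "block_start": False,
        "correct": ch == 1,
        "rt": np.round(np.where(ch >= 0, rt, np.nan), 3),
        "iti": 0.7,
        "lapse_flag": False,
        "coins": 0,
    })


def _bonus(trial_type: str, rt: float, criterion: float, two_sided: bool,
           stacked: bool) -> int:
    def within(pct):
        hi = criterion * (1.0 + pct)
        if rt > hi:
            return False
        if two_sided and rt < criterion * (1.0 - pct):
            return False
        return True

    if trial_type == "switch":
        if within(0.05):
            return 4 if stacked else 3
        if within(0.20):
            return 1
        return 0
    return 1 if within(0.05) else 0


def assign_feedback_coins(trial, config: SessionConfig) -> int:
    """Coins for one resolved trial record (mapping-like with
    ``trial_type``, ``correct`` and ``rt`` fields).

    NFB and AFB award no coins (AFB signals correctness only).  DFB pays
    1 coin for a correct response plus speed bonuses against the 600-ms
    criterion (switch trials: +1 within 20%, +3 within 5%; non-switch:
    +1 within 5%).  PFB, MFB and BFB add a -1 coin punishment for
    incorrect (and omitted) responses; MFB additionally values each coin
    at 0.2 cents and BFB reports a per-block coin summary
    (:func:`bfb_block_summary`).
    """
    cond = config.condition
    if cond not in CONDITIONS:
        raise ConfigError([f"unknown condition {cond!r}"])
    if cond in ("NFB", "AFB"):
        return 0
    try:
        if trial["block_phase"] != "training":
            return 0  # no feedback in pre/post blocks
    except (KeyError, IndexError):
        pass
    correct = bool(trial["correct"]) and np.isfinite(trial["rt"])
    if not correct:
        return -1 if cond in ("PFB", "MFB", "BFB") else 0
    return 1 + _bonus(trial["trial_type"], float(trial["rt"]),
                      config.speed_criterion, config.two_sided_bands,
                      config.stacked_bonus)


def score_coins(trials: pd.DataFrame, config: SessionConfig) -> np.ndarray:
    """Vectorised :func:`assign_feedback_coins` over a trial table."""
    cond = config.condition
    if cond not in CONDITIONS:
        raise ConfigError([f"unknown condition {cond!r}"])
    n = len(trials)
    coins = np.zeros(n, dtype=int)
    if cond in ("NFB", "AFB"):
        return coins
    resolved = trials["rt"].notna().to_numpy()
    correct = trials["correct"].to_numpy(dtype=bool) & resolved
    training = (trials["block_phase"] == "training").to_numpy()
    if cond in ("PFB", "MFB", "BFB"):
        coins[training & ~correct] = -1
    rt = trials["rt"].to_numpy(dtype=float)
    crit = config.speed_criterion
    is_switch = (trials["trial_type"] == "switch").to_numpy()

    def in_band(pct):
        ok = rt <= crit * (1.0 + pct)
        if config.two_sided_bands:
            ok &= rt >= crit * (1.0 - pct)
        return ok

    b5, b20 = in_band(0.05), in_band(0.20)
    bonus = np.zeros(n, dtype=int)
    bonus[is_switch & b20] = 1
    bonus[is_switch & b5] = 4 if config.stacked_bonus else 3
    bonus[~is_switch & b5] = 1
    hit = training & correct
    coins[hit] = 1 + bonus[hit]
    return coins


def bfb_block_summary(trials: pd.DataFrame, config: SessionConfig) -> pd.DataFrame:
    """Per-block percent of attainable coins actually received (the
    end-of-block feedback shown in the BFB scheme)."""
    df = trials[trials["block_phase"] == "training"]
    max_per_trial = np.where(df["trial_type"] == "switch",
                             1 + (4 if config.stacked_bonus else 3), 2)
    got = df.groupby("block_index")["coins"].sum()
    poss = pd.Series(max_per_trial, index=df.index).groupby(df["block_index"]).sum()
    out = pd.DataFrame({"block_index": got.index,
                        "coins": got.to_numpy(),
                        "coins_possible": poss.to_numpy()})
    out["percent_of_total"] = 100.0 * out["coins"] / out["coins_possible"]
    return out.reset_index(drop=True)


def generate_cohort(n_per_condition: dict | None = None,
                    grid: GenerativeGrid | None = None, seed=0,
                    config: SessionConfig | None = None,
                    method: str = "inverse_cdf") -> pd.DataFrame:
    """Simulate a full cohort.

    ``n_per_condition`` maps feedback condition to group size (default:
    the study's 316-subject allocation).  When the grid carries positive
    dispersion each subject's parameters are drawn from the group-level
    distribution.  One master seed drives deterministic per-subject
    substreams, so any subject's data can be regenerated independently.
    """
    from .config import study_grid

    if n_per_condition is None:
        n_per_condition = dict(STUDY_GROUP_SIZES)
    bad = [f"n for {c!r} must be >= 1 (got {n})"
           for c, n in n_per_condition.items() if n < 1]
    bad += [f"unknown condition {c!r}" for c in n_per_condition
            if c not in CONDITIONS]
    if bad:
        raise ConfigError(bad)
    base = config or SessionConfig()
    grid = grid if grid is not None else study_grid(base)
    structure_cache: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence(seed)
    tables = []
    conditions = [c for c in CONDITIONS if c in n_per_condition]
    n_subjects = sum(n_per_condition[c] for c in conditions)
    children = ss.spawn(n_subjects)
    i = 0
    for cond in conditions:
        cfg = SessionConfig(**{**base.__dict__, "condition": cond,
                               "coin_value_cents": None})
        if cond not in structure_cache:
            structure_cache[cond] = build_session_structure(cfg)
        for k in range(1, n_per_condition[cond] + 1):
            child = np.random.default_rng(children[i])
            i += 1
            sgrid = grid.draw_subject(child) if any(
                s > 0 for s in grid.dispersion.values()) else grid
            tables.append(simulate_session(
                structure_cache[cond], sgrid, f"{cond}-{k:03d}",
                child, config=cfg, method=method))
    return pd.concat(tables, ignore_index=True)
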