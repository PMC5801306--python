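"""Fitting diffusion parameter grids to trial tables.

Two fitting routes share one likelihood (the lapse-mixture Wiener
first-passage density, deadline-censored because omissions are removed
before fitting):

* :func:`fit_mle` — deterministic per-subject maximum likelihood with
  bounded multi-start local optimisation; the fast route used by
  parameter-recovery checks.
* :func:`fit_hierarchical` — partial pooling: subject-level parameters
  are drawn from group-level normal distributions whose means and
  spreads are estimated simultaneously, so the group acts as a prior for
  each subject.  Sampling uses an adaptive Metropolis-within-Gibbs
  scheme (random-walk updates per subject x parameter-cell block,
  conjugate draws for group means, Metropolis on log group SDs) with
  multiple chains and split-R-hat convergence diagnostics.

Model variants are declared by :class:`ModelSpec` (which of trial type /
training block condition the drift rate and the boundary; non-decision
time is never conditioned on trial type and the lapse rate is a fixed
constant) and compared by DIC via :func:`compute_dic` /
:func:`compare_models`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._wfpt import loglik_trials, seed_rng, subject_sweep

__all__ = [
    "ModelSpec",
    "SamplerSettings",
    "FitResult",
    "DICEntry",
    "DICResult",
    "model_lattice",
    "fit_mle",
    "fit_hierarchical",
    "compute_dic",
    "compare_models",
]

_FACTORS = ("trial_type", "block")

# fitted parameter ranges (natural scale)
_BOUNDS = {"v": (-8.0, 8.0), "a": (0.2, 6.0), "t0": (0.03, 1.5)}

# weakly-informative group priors: mean prior (m0, tau0) and half-normal
# scale for the group SD
_PRIORS = {"v": ((0.0, 3.0), 1.0),
           "a": ((2.0, 2.0), 1.0),
           "t0": ((0.3, 0.3), 0.2)}


def _norm_cond(cond) -> tuple:
    cond = tuple(c for c in _FACTORS if c in tuple(cond))
    return cond


@dataclass(frozen=True)
class ModelSpec:
    """Which factors condition each diffusion parameter.

    ``v_conditioned_on`` / ``a_conditioned_on`` are subsets of
    {"trial_type", "block"}.  Non-decision time is always shared across
    trial types and blocks; the lapse rate is fixed (default 10%), not
    estimated.
    """

    v_conditioned_on: tuple = ()
    a_conditioned_on: tuple = ()
    lapse: float = 0.10
    label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "v_conditioned_on",
                           _norm_cond(self.v_conditioned_on))
        object.__setattr__(self, "a_conditioned_on",
                           _norm_cond(self.a_conditioned_on))
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    @property
    def name(self) -> str:
        if self.label:
            return self.label

        def fmt(cond):
            return "x".join(cond) if cond else "constant"

        return f"v[{fmt(self.v_conditioned_on)}]_a[{fmt(self.a_conditioned_on)}]"


#: The winning structure of the study: both v and a conditioned on trial
#: type and block.
WINNING_SPEC = ModelSpec(("trial_type", "block"), ("trial_type", "block"))


def model_lattice() -> list[ModelSpec]:
    """All 16 conditioning combinations for (v, a) over
    {trial_type, block}."""
    opts = [(), ("trial_type",), ("block",), ("trial_type", "block")]
    return [ModelSpec(vc, ac) for vc, ac in itertools.product(opts, opts)]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC settings for :func:`fit_hierarchical`."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.35
    adapt_interval: int = 25
    rhat_threshold: float = 1.05
    censor: bool = True


@dataclass
class FitResult:
    """Estimates plus deviance bookkeeping from either fitting route."""

    mode: str
    spec: ModelSpec
    group_summary: pd.DataFrame
    subject_summary: pd.DataFrame
    deadline: float
    deviance: np.ndarray | None = None  # (chains, draws)
    deviance_at_mean: float | None = None
    loglik: float | None = None
    diagnostics: dict = field(default_factory=dict)
    unestimable: list = field(default_factory=list)
    seed: int | None = None

    @property
    def converged(self) -> bool | None:
        return self.diagnostics.get("converged")

    def cell_estimates(self, param: str, level: str = "group") -> pd.DataFrame:
        df = self.group_summary if level == "group" else self.subject_summary
        return df[df["param"] == param].reset_index(drop=True)


@dataclass(frozen=True)
class DICEntry:
    model: str
    dic: float
    mean_deviance: float
    p_d: float
    error: str | None = None


@dataclass
class DICResult:
    """Model-comparison table; winner is the minimum-DIC model, ties
    broken by declaration order and reported."""

    table: pd.DataFrame
    winner: str
    is_tie: bool = False
    failures: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data packing

def _key_of(cond, tt, blk):
    out = []
    if "trial_type" in cond:
        out.append(tt)
    if "block" in cond:
        out.append(int(blk))
    return tuple(out)


def _labels_of(cond, key) -> dict:
    lab = {"trial_type": None, "block": None}
    for f, val in zip(cond, key):
        lab[f] = val
    return lab


@dataclass
class _Packed:
    subject_id: str
    rt: np.ndarray
    correct: np.ndarray
    cstart: np.ndarray
    c_vidx: np.ndarray
    c_aidx: np.ndarray
    n_resolved: int


def _pack(trials: pd.DataFrame, spec: ModelSpec):
    """Index trials by (v-cell, a-cell) joint cells per subject."""
    resolved = trials[trials["rt"].notna()]
    if len(resolved) == 0:
        raise ValueError("no resolved trials to fit")
    tts = resolved["trial_type"].to_numpy()
    blks = resolved["block_index"].to_numpy()
    v_keys = sorted({_key_of(spec.v_conditioned_on, tt, b)
                     for tt, b in zip(tts, blks)})
    a_keys = sorted({_key_of(spec.a_conditioned_on, tt, b)
                     for tt, b in zip(tts, blks)})
    v_index = {k: i for i, k in enumerate(v_keys)}
    a_index = {k: i for i, k in enumerate(a_keys)}
    packed = []
    for sid, sub in resolved.groupby("subject_id", sort=True):
        vi = np.array([v_index[_key_of(spec.v_conditioned_on, tt, b)]
                       for tt, b in zip(sub["trial_type"], sub["block_index"])])
        ai = np.array([a_index[_key_of(spec.a_conditioned_on, tt, b)]
                       for tt, b in zip(sub["trial_type"], sub["block_index"])])
        joint = vi * (len(a_keys) + 1) + ai
        order = np.argsort(joint, kind="stable")
        joint_sorted = joint[order]
        uniq, starts = np.unique(joint_sorted, return_index=True)
        cstart = np.append(starts, len(joint_sorted)).astype(np.int64)
        c_vidx = (uniq // (len(a_keys) + 1)).astype(np.int64)
        c_aidx = (uniq % (len(a_keys) + 1)).astype(np.int64)
        packed.append(_Packed(
            subject_id=str(sid),
            rt=sub["rt"].to_numpy(dtype=float)[order],
            correct=sub["correct"].to_numpy(dtype=bool).astype(np.int8)[order],
            cstart=cstart, c_vidx=c_vidx, c_aidx=c_aidx,
            n_resolved=len(sub)))
    return packed, v_keys, a_keys


def _summary_rows(spec, v_keys, a_keys, row_fn):
    rows = []
    for param, keys, cond in (("v", v_keys, spec.v_conditioned_on),
                              ("a", a_keys, spec.a_conditioned_on),
                              ("t0", [()], ())):
        for j, key in enumerate(keys):
            lab = _labels_of(cond, key)
            rows.append({"param": param, **lab, **row_fn(param, j)})
    return rows


# ---------------------------------------------------------------------------
# maximum likelihood

def fit_mle(trials: pd.DataFrame, spec: ModelSpec | None = None,
            deadline: float = 2.0, trial_floor: int = 40,
            censor: bool = True, n_starts: int = 5,
            fix_t0: float | None = None) -> FitResult:
    """Per-subject maximum likelihood under ``spec``.

    Joint (v-cell, a-cell) cells with fewer than ``trial_floor`` resolved
    trials are flagged unestimable and excluded from the likelihood (not
    silently dropped); a parameter with no estimable cell left is
    reported as NaN.  Deterministic given the data and optimiser
    settings.

    ``fix_t0`` pins the non-decision time instead of estimating it:
    useful in recovery experiments where t0 is a known given, since the
    boundary and t0 estimates trade off strongly in high-accuracy cells.
    """
    spec = spec or ModelSpec()
    packed, v_keys, a_keys = _pack(trials, spec)
    nv, na = len(v_keys), len(a_keys)
    sub_rows = []
    unestimable = []
    total_ll = 0.0
    for p in packed:
        counts = np.diff(p.cstart)
        ok_cells = counts >= trial_floor
        for c in np.flatnonzero(~ok_cells):
            unestimable.append({
                "subject_id": p.subject_id,
                "v_cell": _labels_of(spec.v_conditioned_on, v_keys[p.c_vidx[c]]),
                "a_cell": _labels_of(spec.a_conditioned_on, a_keys[p.c_aidx[c]]),
                "n_resolved": int(counts[c])})
        est, ll = _mle_one(p, ok_cells, nv, na, spec.lapse, deadline,
                           censor, n_starts, fix_t0)
        total_ll += ll if np.isfinite(ll) else 0.0
        v_hat, a_hat, t0_hat = est

        def row_fn(param, j):
            if param == "v":
                val = v_hat[j]
            elif param == "a":
                val = a_hat[j]
            else:
                val = t0_hat
            return {"subject_id": p.subject_id, "estimate": float(val)}

        sub_rows.extend(_summary_rows(spec, v_keys, a_keys, row_fn))
    subject_summary = pd.DataFrame(sub_rows)
    group_summary = (subject_summary
                     .groupby(["param", "trial_type", "block"], dropna=False)
                     ["estimate"].mean().reset_index())
    return FitResult(mode="mle", spec=spec, group_summary=group_summary,
                     subject_summary=subject_summary, deadline=deadline,
                     loglik=total_ll,
                     diagnostics={"n_subjects": len(packed),
                                  "n_starts": n_starts,
                                  "trial_floor": trial_floor},
                     unestimable=unestimable)


def _neg_ll(theta, p: _Packed, ok_cells, nv, na, lapse, deadline, censor):
    v = theta[:nv]
    a = theta[nv:nv + na]
    t0 = theta[-1]
    total = 0.0
    for c in range(len(p.c_vidx)):
        if not ok_cells[c]:
            continue
        ll = loglik_trials(p.rt[p.cstart[c]:p.cstart[c + 1]],
                           p.correct[p.cstart[c]:p.cstart[c + 1]],
                           v[p.c_vidx[c]], a[p.c_aidx[c]], t0,
                           lapse, deadline, censor)
        if not np.isfinite(ll):
            return 1e12
        total += ll
    return -total


def _mle_one(p: _Packed, ok_cells, nv, na, lapse, deadline, censor, n_starts,
             fix_t0=None):
    active_v = sorted({p.c_vidx[c] for c in np.flatnonzero(ok_cells)})
    active_a = sorted({p.c_aidx[c] for c in np.flatnonzero(ok_cells)})
    if not active_v:
        return (np.full(nv, np.nan), np.full(na, np.nan), np.nan), np.nan
    # data-informed anchors: accuracy of each v-cell pins v*a through the
    # logistic choice identity; early RT quantile anchors t0
    acc_v = np.full(nv, 0.75)
    for j in active_v:
        sel = np.concatenate([
            p.correct[p.cstart[c]:p.cstart[c + 1]]
            for c in np.flatnonzero(ok_cells) if p.c_vidx[c] == j])
        acc_v[j] = np.clip(sel.mean(), 0.05, 0.98)
    rt_min = float(np.quantile(p.rt, 0.05))
    t0_anchor = float(np.clip(0.7 * rt_min, *_BOUNDS["t0"]))
    starts = []
    for k, (a0, t0s) in enumerate(
            [(2.0, t0_anchor), (1.2, t0_anchor), (3.0, 0.5 * t0_anchor),
             (2.0, min(t0_anchor + 0.1, _BOUNDS["t0"][1])), (1.6, 0.15)][:n_starts]):
        va = np.log(acc_v / (1 - acc_v))
        v0 = np.clip(va / a0, -6, 6)
        theta0 = np.concatenate([v0, np.full(na, a0), [t0s]])
        starts.append(theta0)
    lb = np.concatenate([np.full(nv, _BOUNDS["v"][0]),
                         np.full(na, _BOUNDS["a"][0]), [_BOUNDS["t0"][0]]])
    ub = np.concatenate([np.full(nv, _BOUNDS["v"][1]),
                         np.full(na, _BOUNDS["a"][1]),
                         [min(_BOUNDS["t0"][1], deadline - 1e-3)]])
    if fix_t0 is not None:
        lb[-1] = ub[-1] = float(fix_t0)
    best = None
    for theta0 in starts:
        res = optimize.minimize(
            _neg_ll, np.clip(theta0, lb, ub),
            args=(p, ok_cells, nv, na, lapse, deadline, censor),
            method="L-BFGS-B", bounds=list(zip(lb, ub)))
        if best is None or res.fun < best.fun:
            best = res
    v = np.full(nv, np.nan)
    a = np.full(na, np.nan)
    v[active_v] = best.x[:nv][active_v]
    a[active_a] = best.x[nv:nv + na][active_a]
    return (v, a, float(best.x[-1])), -float(best.fun)


# ---------------------------------------------------------------------------
# hierarchical Bayes

def fit_hierarchical(trials: pd.DataFrame, spec: ModelSpec | None = None,
                     settings: SamplerSettings | None = None, seed: int = 0,
                     deadline: float = 2.0) -> FitResult:
    """Hierarchical Bayesian fit: subject parameters partially pooled
    through group-level normal distributions.

    Requires at least two subjects (a single subject has no group to
    pool over: use :func:`fit_mle`).  Identical seed and settings give
    identical posterior summaries.  Non-convergence (split-R-hat above
    the threshold on any group parameter) flags the result; it is never
    silently accepted.
    """
    spec = spec or ModelSpec()
    settings = settings or SamplerSettings()
    packed, v_keys, a_keys = _pack(trials, spec)
    if len(packed) < 2:
        raise ValueError(
            "hierarchical fitting needs >= 2 subjects; use fit_mle for a "
            "single subject")
    nv, na, S = len(v_keys), len(a_keys), len(packed)
    ss = np.random.SeedSequence([int(seed) % (2**31), 17])
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(settings.n_chains)]
    chains = [_run_chain(packed, nv, na, spec.lapse, deadline, settings, cs)
              for cs in chain_seeds]
    result = _summarise_chains(chains, packed, spec, v_keys, a_keys,
                               settings, deadline)
    result.seed = int(seed)
    return result


def _init_state(packed, nv, na, rng):
    S = len(packed)
    v = np.zeros((S, nv))
    a = np.full((S, na), 2.0)
    t0 = np.zeros(S)
    for i, p in enumerate(packed):
        acc = np.full(nv, 0.75)
        cnt = np.zeros(nv)
        for c in range(len(p.c_vidx)):
            sl = p.correct[p.cstart[c]:p.cstart[c + 1]]
            j = p.c_vidx[c]
            acc[j] = (acc[j] * cnt[j] + sl.sum()) / (cnt[j] + len(sl))
            cnt[j] += len(sl)
        acc = np.clip(acc, 0.05, 0.98)
        a[i] += rng.normal(0, 0.15, na)
        a[i] = np.clip(a[i], 0.5, 5.0)
        v[i] = np.clip(np.log(acc / (1 - acc)) / a[i].mean(), -6, 6) \
            + rng.normal(0, 0.1, nv)
        t0[i] = np.clip(0.7 * np.quantile(p.rt, 0.05) + rng.normal(0, 0.02),
                        0.05, 0.8)
    return v, a, t0


def _run_chain(packed, nv, na, lapse, deadline, settings: SamplerSettings,
               chain_seed: int):
    rng = np.random.default_rng(chain_seed)
    seed_rng(int(rng.integers(0, 2**31 - 1)))
    S = len(packed)
    v, a, t0 = _init_state(packed, nv, na, rng)
    mu_v = v.mean(axis=0)
    sd_v = np.maximum(v.std(axis=0), 0.15)
    mu_a = a.mean(axis=0)
    sd_a = np.maximum(a.std(axis=0), 0.15)
    mu_t0 = np.array([t0.mean()])
    sd_t0 = np.array([max(t0.std(), 0.03)])
    censor = settings.censor
    # per-subject proposal scales and acceptance accumulators
    sc_v = [np.full(nv, 0.25) for _ in range(S)]
    sc_a = [np.full(na, 0.25) for _ in range(S)]
    sc_t0 = [np.array([0.02]) for _ in range(S)]
    acc = [np.zeros(8) for _ in range(S)]
    shift_sc_v = np.full(nv, 0.08)
    shift_sc_a = np.full(na, 0.08)
    shift_acc_v = np.zeros((nv, 2))
    shift_acc_a = np.zeros((na, 2))
    ncells = [len(p.c_vidx) for p in packed]
    joint_lam = [np.full(nc, 1.2) for nc in ncells]
    joint_acc = [np.zeros((nc, 2)) for nc in ncells]
    stat_n = [np.zeros(1) for _ in range(S)]
    stat_mean = [np.zeros((nc, 2)) for nc in ncells]
    stat_m2 = [np.zeros((nc, 2, 2)) for nc in ncells]
    cell_ll = []
    for i, p in enumerate(packed):
        ll = np.empty(len(p.c_vidx))
        for c in range(len(p.c_vidx)):
            ll[c] = loglik_trials(p.rt[p.cstart[c]:p.cstart[c + 1]],
                                  p.correct[p.cstart[c]:p.cstart[c + 1]],
                                  v[i, p.c_vidx[c]], a[i, p.c_aidx[c]], t0[i],
                                  lapse, deadline, censor)
        cell_ll.append(ll)
    vlo, vhi = _BOUNDS["v"]
    alo, ahi = _BOUNDS["a"]
    t0lo, t0hi = _BOUNDS["t0"][0], min(_BOUNDS["t0"][1], deadline - 1e-3)
    n_total = settings.n_warmup + settings.n_draws
    draws = {"mu_v": np.empty((settings.n_draws, nv)),
             "sd_v": np.empty((settings.n_draws, nv)),
             "mu_a": np.empty((settings.n_draws, na)),
             "sd_a": np.empty((settings.n_draws, na)),
             "mu_t0": np.empty((settings.n_draws, 1)),
             "sd_t0": np.empty((settings.n_draws, 1)),
             "subj_v": np.empty((settings.n_draws, S, nv)),
             "subj_a": np.empty((settings.n_draws, S, na)),
             "subj_t0": np.empty((settings.n_draws, S)),
             "deviance": np.empty(settings.n_draws)}
    t0_arrs = [np.array([t0[i]]) for i in range(S)]
    for sweep in range(n_total):
        for i, p in enumerate(packed):
            subject_sweep(p.rt, p.correct, p.cstart, p.c_vidx, p.c_aidx,
                          v[i], a[i], t0_arrs[i], cell_ll[i],
                          mu_v, sd_v, mu_a, sd_a, mu_t0, sd_t0,
                          sc_v[i], sc_a[i], sc_t0[i],
                          joint_lam[i], joint_acc[i], stat_n[i],
                          stat_mean[i], stat_m2[i],
                          lapse, deadline, censor,
                          vlo, vhi, alo, ahi, t0lo, t0hi,
                          acc[i], 0)
        t0 = np.array([ta[0] for ta in t0_arrs])
        mu_v, sd_v = _group_update(v, mu_v, sd_v, *_PRIORS["v"], rng)
        mu_a, sd_a = _group_update(a, mu_a, sd_a, *_PRIORS["a"], rng)
        mu_t0, sd_t0 = _group_update(t0[:, None], mu_t0, sd_t0,
                                     *_PRIORS["t0"], rng)
        # shift moves: translate a group mean together with every
        # subject's value for that cell.  In the centered
        # parametrisation the group mean otherwise only moves at the
        # pace of subject-level drift, which mixes poorly for weakly
        # identified cells.
        _shift_move(packed, v, "v", mu_v, sd_v, a, t0, cell_ll,
                    shift_sc_v, shift_acc_v, lapse, deadline, censor,
                    (vlo, vhi), _PRIORS["v"][0], rng)
        _shift_move(packed, a, "a", mu_a, sd_a, v, t0, cell_ll,
                    shift_sc_a, shift_acc_a, lapse, deadline, censor,
                    (alo, ahi), _PRIORS["a"][0], rng)
        if sweep < settings.n_warmup:
            if sweep == settings.n_warmup // 3:
                # drop the initial transient from the covariance estimate
                for i in range(S):
                    stat_n[i][:] = 0.0
                    stat_mean[i][:] = 0.0
                    stat_m2[i][:] = 0.0
            if (sweep + 1) % settings.adapt_interval == 0:
                for i in range(S):
                    _adapt(sc_v[i], acc[i][0], acc[i][1], settings.target_accept)
                    _adapt(sc_a[i], acc[i][2], acc[i][3], settings.target_accept)
                    _adapt(sc_t0[i], acc[i][4], acc[i][5], settings.target_accept)
                    acc[i][:] = 0.0
                    with np.errstate(invalid="ignore"):
                        rate = np.where(joint_acc[i][:, 1] > 0,
                                        joint_acc[i][:, 0]
                                        / np.maximum(joint_acc[i][:, 1], 1.0),
                                        settings.target_accept)
                    joint_lam[i] *= np.exp(np.clip(
                        rate - settings.target_accept, -0.5, 0.5))
                    np.clip(joint_lam[i], 0.05, 10.0, out=joint_lam[i])
                    joint_acc[i][:] = 0.0
                for sc, counts in ((shift_sc_v, shift_acc_v),
                                   (shift_sc_a, shift_acc_a)):
                    rate = np.where(counts[:, 1] > 0,
                                    counts[:, 0] / np.maximum(counts[:, 1], 1.0),
                                    settings.target_accept)
                    sc *= np.exp(np.clip(rate - settings.target_accept,
                                         -0.5, 0.5))
                    np.clip(sc, 1e-3, 1.0, out=sc)
                    counts[:] = 0.0
        else:
            d = sweep - settings.n_warmup
            draws["mu_v"][d] = mu_v
            draws["sd_v"][d] = sd_v
            draws["mu_a"][d] = mu_a
            draws["sd_a"][d] = sd_a
            draws["mu_t0"][d] = mu_t0
            draws["sd_t0"][d] = sd_t0
            for i in range(S):
                draws["subj_v"][d, i] = v[i]
                draws["subj_a"][d, i] = a[i]
                draws["subj_t0"][d, i] = t0_arrs[i][0]
            draws["deviance"][d] = -2.0 * sum(float(ll.sum()) for ll in cell_ll)
    return draws


def _shift_move(packed, values, family, mu, sd, other, t0, cell_ll,
                scales, counts, lapse, deadline, censor, bounds, mean_prior,
                rng):
    """Metropolis translation of one group mean plus all subject values
    for that cell (subject deviations, and hence the group-SD terms,
    are unchanged; only the trial likelihoods and the group-mean prior
    move)."""
    m0, tau0 = mean_prior
    lo, hi = bounds
    S = len(packed)
    for j in range(values.shape[1]):
        counts[j, 1] += 1.0
        d = rng.standard_normal() * scales[j]
        col = values[:, j]
        if (col + d).min() < lo or (col + d).max() > hi:
            continue
        newmu = mu[j] + d
        delta = (-0.5 * ((newmu - m0) / tau0) ** 2
                 + 0.5 * ((mu[j] - m0) / tau0) ** 2)
        new_lls = []
        for i, p in enumerate(packed):
            for c in range(len(p.c_vidx)):
                hit = (p.c_vidx[c] == j) if family == "v" else (p.c_aidx[c] == j)
                if not hit:
                    continue
                if family == "v":
                    vv = values[i, j] + d
                    aa = other[i, p.c_aidx[c]]
                else:
                    vv = other[i, p.c_vidx[c]]
                    aa = values[i, j] + d
                ll = loglik_trials(p.rt[p.cstart[c]:p.cstart[c + 1]],
                                   p.correct[p.cstart[c]:p.cstart[c + 1]],
                                   vv, aa, t0[i], lapse, deadline, censor)
                new_lls.append((i, c, ll))
                delta += ll - cell_ll[i][c]
        if math.log(rng.random() + 1e-300) < delta:
            mu[j] = newmu
            values[:, j] += d
            for i, c, ll in new_lls:
                cell_ll[i][c] = ll
            counts[j, 0] += 1.0


def _adapt(scales, n_acc, n_try, target):
    if n_try <= 0:
        return
    rate = n_acc / n_try
    scales *= math.exp(np.clip(rate - target, -0.5, 0.5))
    np.clip(scales, 1e-4, 3.0, out=scales)


def _group_update(values, mu, sd, mean_prior, sd_scale, rng):
    """Conjugate draw of the group mean, Metropolis on log group SD."""
    m0, tau0 = mean_prior
    S, k = values.shape
    mu = mu.copy()
    sd = sd.copy()
    for j in range(k):
        x = values[:, j]
        prec = S / sd[j] ** 2 + 1.0 / tau0 ** 2
        mean = (x.sum() / sd[j] ** 2 + m0 / tau0 ** 2) / prec
        mu[j] = rng.normal(mean, 1.0 / math.sqrt(prec))
        prop = sd[j] * math.exp(0.15 * rng.standard_normal())

        def lp(s):
            return (-S * math.log(s) - ((x - mu[j]) ** 2).sum() / (2 * s * s)
                    - s * s / (2 * sd_scale ** 2) + math.log(s))

        if math.log(rng.random() + 1e-300) < lp(prop) - lp(sd[j]):
            sd[j] = prop
        sd[j] = max(sd[j], 1e-3)
    return mu, sd


def _summarise_chains(chains, packed, spec, v_keys, a_keys,
                      settings: SamplerSettings, deadline) -> FitResult:
    import arviz as az

    nv, na, S = len(v_keys), len(a_keys), len(packed)

    def stack(name):
        return np.stack([c[name] for c in chains])  # (chain, draw, ...)

    group_rows = []
    rhats = {}
    for param, keys, mu_name, sd_name in (("v", v_keys, "mu_v", "sd_v"),
                                          ("a", a_keys, "mu_a", "sd_a"),
                                          ("t0", [()], "mu_t0", "sd_t0")):
        mu = stack(mu_name)
        sdd = stack(sd_name)
        cond = {"v": spec.v_conditioned_on, "a": spec.a_conditioned_on,
                "t0": ()}[param]
        for j, key in enumerate(keys):
            tr = mu[:, :, j]
            rhat = float(np.asarray(
                az.rhat(az.convert_to_dataset(tr)).to_array()).ravel()[0])
            rhats[f"mu_{param}[{j}]"] = rhat
            flat = tr.reshape(-1)
            sd_flat = sdd[:, :, j].reshape(-1)
            group_rows.append({
                "param": param, **_labels_of(cond, key),
                "mean": float(flat.mean()), "sd": float(flat.std()),
                "ci_low": float(np.quantile(flat, 0.025)),
                "ci_high": float(np.quantile(flat, 0.975)),
                "group_sd_mean": float(sd_flat.mean()),
                "rhat": rhat})
    group_summary = pd.DataFrame(group_rows)
    subj_v = stack("subj_v")
    subj_a = stack("subj_a")
    subj_t0 = stack("subj_t0")
    sub_rows = []
    for i, p in enumerate(packed):
        def row_fn(param, j, i=i):
            if param == "v":
                tr = subj_v[:, :, i, j]
            elif param == "a":
                tr = subj_a[:, :, i, j]
            else:
                tr = subj_t0[:, :, i]
            flat = tr.reshape(-1)
            return {"subject_id": p.subject_id,
                    "estimate": float(flat.mean()),
                    "sd": float(flat.std()),
                    "ci_low": float(np.quantile(flat, 0.025)),
                    "ci_high": float(np.quantile(flat, 0.975))}

        sub_rows.extend(_summary_rows(spec, v_keys, a_keys, row_fn))
    subject_summary = pd.DataFrame(sub_rows)
    deviance = stack("deviance")
    # deviance at the posterior mean of the subject-level parameters
    d_at_mean = 0.0
    for i, p in enumerate(packed):
        v_hat = subj_v[:, :, i, :].reshape(-1, nv).mean(axis=0)
        a_hat = subj_a[:, :, i, :].reshape(-1, na).mean(axis=0)
        t0_hat = float(subj_t0[:, :, i].mean())
        for c in range(len(p.c_vidx)):
            d_at_mean += loglik_trials(
                p.rt[p.cstart[c]:p.cstart[c + 1]],
                p.correct[p.cstart[c]:p.cstart[c + 1]],
                v_hat[p.c_vidx[c]], a_hat[p.c_aidx[c]], t0_hat,
                spec.lapse, deadline, settings.censor)
    d_at_mean *= -2.0
    max_rhat = max(rhats.values())
    diagnostics = {"n_chains": settings.n_chains,
                   "n_draws": settings.n_draws,
                   "n_warmup": settings.n_warmup,
                   "rhat": rhats,
                   "max_rhat": max_rhat,
                   "converged": bool(max_rhat < settings.rhat_threshold),
                   "n_subjects": S}
    return FitResult(mode="hierarchical", spec=spec,
                     group_summary=group_summary,
                     subject_summary=subject_summary, deadline=deadline,
                     deviance=deviance, deviance_at_mean=float(d_at_mean),
                     diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# DIC

def compute_dic(fit: FitResult, p_d_variant: str = "spiegelhalter") -> DICEntry:
    """DIC = mean posterior deviance + effective number of parameters.

    ``p_d_variant`` selects the classic definition
    ``p_D = mean(D) - D(posterior mean)`` or the variance-based
    alternative ``p_D = var(D) / 2``.
    """
    if fit.deviance is None:
        raise ValueError("fit carries no posterior deviance trace "
                         "(hierarchical mode required)")
    dbar = float(fit.deviance.mean())
    if p_d_variant == "spiegelhalter":
        p_d = dbar - float(fit.deviance_at_mean)
    elif p_d_variant == "variance":
        p_d = float(fit.deviance.var()) / 2.0
    else:
        raise ValueError(f"unknown p_d variant {p_d_variant!r}")
    return DICEntry(model=fit.spec.name, dic=dbar + p_d, mean_deviance=dbar,
                    p_d=p_d)


def compare_models(trials: pd.DataFrame, specs, mode: str = "hierarchical",
                   settings: SamplerSettings | None = None, seed: int = 0,
                   deadline: float = 2.0,
                   p_d_variant: str = "spiegelhalter") -> DICResult:
    """Fit every spec and tabulate DIC; the winner has minimum DIC.

    Fit failures are recorded per spec, never silently dropped."""
    import zlib

    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("model comparison needs at least two specs")
    entries = []
    failures = {}
    for spec in specs:
        # seed derived from the spec name: a duplicated spec reproduces
        # the identical fit, so duplicates tie exactly
        sub_seed = ((int(seed) % (2**31)) * 2654435761
                    ^ zlib.crc32(spec.name.encode())) % (2**31 - 1)
        try:
            fit = fit_hierarchical(trials, spec, settings=settings,
                                   seed=sub_seed, deadline=deadline)
            entries.append(compute_dic(fit, p_d_variant))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            failures[spec.name] = str(exc)
            entries.append(DICEntry(model=spec.name, dic=float("inf"),
                                    mean_deviance=float("nan"),
                                    p_d=float("nan"), error=str(exc)))
    table = pd.DataFrame([e.__dict__ for e in entries])
    finite = table["dic"].to_numpy()
    best = int(np.argmin(finite))
    is_tie = bool(np.sum(finite == finite[best]) > 1)
    return DICResult(table=table, winner=entries[best].model, is_tie=is_tie,
                     failures=failures)
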