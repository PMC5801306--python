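"""Two-boundary drift-diffusion machinery.

The decision process is a noisy accumulator
``W(t + dt) = W(t) + v * dt + noise`` between absorbing boundaries at 0
(incorrect) and ``a`` (correct), started unbiased at ``a / 2`` with unit
diffusion noise (s = 1 per root-second, so printed drift/boundary
magnitudes of 2-3 are the natural scale).  Observed response time is the
first-passage time plus a non-decision latency ``t0``; a fixed fraction
``lapse`` of responses is instead drawn uniformly over choices and over
time up to the response deadline, absorbing fast guesses and attentional
lapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._wfpt import (
    euler_walks,
    loglik_trials,
    wfpt_pdf_grid,
    wfpt_survival,
)

__all__ = [
    "DDMParams",
    "ChoiceRT",
    "choice_probability",
    "observed_accuracy",
    "fpt_density",
    "fpt_mass_within",
    "lapse_likelihood",
    "simulate_walk",
    "simulate_walks",
    "sample_first_passage",
    "ddm_check",
]


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one condition cell.

    v : drift rate, evidence per second, signed toward the correct boundary
    a : boundary separation, evidence units (> 0)
    t0 : non-decision time, seconds (>= 0)
    lapse : uniform-contaminant mixture weight in [0, 1]

    The starting point is fixed at ``a / 2`` and the noise scale at 1;
    neither is a free parameter.
    """

    v: float
    a: float
    t0: float = 0.3
    lapse: float = 0.10

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError("drift rate v must be finite")
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError("boundary separation a must be positive and finite")
        if not (np.isfinite(self.t0) and self.t0 >= 0):
            raise ValueError("non-decision time t0 must be >= 0")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")

    @property
    def z(self) -> float:
        """Starting point (always a/2: responses are coded correct/incorrect)."""
        return self.a / 2.0


@dataclass(frozen=True)
class ChoiceRT:
    """A single simulated response.

    choice : "upper" (correct), "lower" (incorrect) or "none" (deadline
        reached without absorption)
    rt : seconds from stimulus onset, including non-decision time
        (nan when choice == "none")
    """

    choice: str
    rt: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.choice not in ("upper", "lower", "none"):
            raise ValueError(f"unknown choice {self.choice!r}")


def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper (correct) boundary, pre-lapse.

    For start a/2 and unit noise this is the logistic identity
    ``1 / (1 + exp(-v * a))``.
    """
    return 1.0 / (1.0 + math.exp(-params.v * params.a))


def observed_accuracy(params: DDMParams) -> float:
    """Expected accuracy including the lapse mixture:
    ``(1 - lapse) * P(correct) + lapse / 2``."""
    return (1.0 - params.lapse) * choice_probability(params) + params.lapse / 2.0


def fpt_density(t, choice, params: DDMParams):
    """First-passage density of the diffusion component at stimulus RT ``t``.

    ``t`` is measured from stimulus onset; the density is zero at or below
    ``t0``.  ``choice`` is "upper" or "lower".  Accepts a scalar or array.
    """
    if choice not in ("upper", "lower"):
        raise ValueError("choice must be 'upper' or 'lower'")
    for name, val in (("v", params.v), ("a", params.a), ("t0", params.t0)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite parameter {name}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    tdec = t_arr - params.t0
    up, lo = wfpt_pdf_grid(tdec, params.v, params.a)
    out = up if choice == "upper" else lo
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def fpt_mass_within(params: DDMParams, deadline: float) -> float:
    """Diffusion mass absorbed (either boundary) before the deadline."""
    if deadline <= 0:
        raise ValueError("deadline must be positive")
    Td = deadline - params.t0
    if Td <= 0:
        return 0.0
    return 1.0 - wfpt_survival(Td, params.v, params.a)


def lapse_likelihood(datum: ChoiceRT, params: DDMParams, deadline: float,
                     censor: bool = False) -> float:
    """Likelihood of one resolved response under the lapse mixture:
    ``(1 - lapse) * fpt_density + lapse / (2 * deadline)``.

    With ``censor`` the diffusion component is renormalised to the mass
    resolving before the deadline (use when omissions were removed from
    the data)."""
    if deadline <= 0:
        raise ValueError("deadline must be positive")
    if datum.choice == "none":
        raise ValueError("lapse_likelihood is defined for resolved trials only")
    rt = np.asarray([datum.rt], dtype=float)
    correct = np.asarray([1 if datum.choice == "upper" else 0], dtype=np.int8)
    ll = loglik_trials(rt, correct, params.v, params.a, params.t0,
                       params.lapse, deadline, censor)
    return float(np.exp(ll))


def simulate_walk(params: DDMParams, dt: float = 1e-4, deadline: float = 2.0,
                  seed: int = 0) -> ChoiceRT:
    """Euler-Maruyama simulation of a single trial (lapse mixture included)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= deadline:
        raise ValueError("dt must be smaller than the deadline")
    if deadline <= params.t0:
        raise ValueError("deadline must exceed the non-decision time")
    choice, rt = euler_walks(params.v, params.a, params.t0, params.lapse,
                             1, dt, deadline, _as_seed(seed))
    label = {1: "upper", 0: "lower", -1: "none"}[int(choice[0])]
    return ChoiceRT(label, float(rt[0]))


def simulate_walks(params: DDMParams, n: int, dt: float = 1e-4,
                   deadline: float = 2.0, seed: int = 0):
    """Vectorised Euler-Maruyama simulation of ``n`` trials.

    Returns ``(choice, rt)`` arrays: choice 1 = correct, 0 = error,
    -1 = omission (rt = nan)."""
    if dt <= 0 or dt >= deadline:
        raise ValueError("require 0 < dt < deadline")
    if deadline <= params.t0:
        raise ValueError("deadline must exceed the non-decision time")
    return euler_walks(params.v, params.a, params.t0, params.lapse,
                       int(n), dt, deadline, _as_seed(seed))


def sample_first_passage(params: DDMParams, n: int, deadline: float = 2.0,
                         rng=None, n_grid: int = 2048):
    """Draw ``n`` (choice, rt) pairs from the lapse-mixture diffusion by
    inverting the first-passage CDF on a time grid (exact up to grid
    interpolation; the fast path used by the session generator).

    Returns ``(choice, rt)`` with the same coding as :func:`simulate_walks`.
    """
    if deadline <= params.t0:
        raise ValueError("deadline must exceed the non-decision time")
    rng = np.random.default_rng(rng)
    Td = deadline - params.t0
    tgrid = np.linspace(0.0, Td, n_grid + 1)
    up, lo = wfpt_pdf_grid(tgrid, params.v, params.a)
    cup = _cumtrapz(up, tgrid)
    clo = _cumtrapz(lo, tgrid)
    mass_resolved = 1.0 - wfpt_survival(Td, params.v, params.a)
    # guard against quadrature drift: scale the grid CDFs to the analytic mass
    tot = cup[-1] + clo[-1]
    if tot > 0 and mass_resolved > 0:
        scale = mass_resolved / tot
        cup *= scale
        clo *= scale
    choice = np.empty(n, dtype=np.int8)
    rt = np.full(n, np.nan)
    is_lapse = rng.random(n) < params.lapse
    nl = int(is_lapse.sum())
    if nl:
        choice[is_lapse] = (rng.random(nl) < 0.5).astype(np.int8)
        u = rng.random(nl) * deadline
        u[u == 0.0] = deadline * 0.5 / n_grid
        rt[is_lapse] = u
    idx = ~is_lapse
    nd = int(idx.sum())
    if nd:
        u = rng.random(nd)
        c = np.full(nd, -1, dtype=np.int8)
        t = np.full(nd, np.nan)
        upper_mask = u < cup[-1]
        lower_mask = (~upper_mask) & (u < cup[-1] + clo[-1])
        if upper_mask.any():
            t[upper_mask] = np.interp(u[upper_mask], cup, tgrid)
            c[upper_mask] = 1
        if lower_mask.any():
            t[lower_mask] = np.interp(u[lower_mask] - cup[-1], clo, tgrid)
            c[lower_mask] = 0
        resolved = c >= 0
        t[resolved] = np.maximum(t[resolved], Td * 0.5 / n_grid)
        choice[idx] = c
        rt[idx] = np.where(resolved, params.t0 + t, np.nan)
    return choice, rt


def ddm_check(seed: int = 0, n_walks: int = 50_000, dt: float = 1e-3,
              grid=None) -> dict:
    """Self-diagnostic: density normalisation across the fitted parameter
    range and simulator-vs-density CDF agreement on a (v, a) grid.

    Returns a report dict with per-check numbers and pass flags.  The full
    acceptance-strength version (dt = 1e-4, n = 5e4) is what the test
    suite runs; the defaults here are a faster smoke check.
    """
    report = {"normalization": [], "oracle": []}
    for v in (-5.0, -2.0, 0.0, 2.58, 5.0):
        for a in (0.5, 1.0, 2.0, 4.0):
            p = DDMParams(v=v, a=a, t0=0.0, lapse=0.0)
            mass = _total_mass(p)
            report["normalization"].append(
                {"v": v, "a": a, "mass": mass, "ok": bool(abs(mass - 1.0) < 1e-4)})
    if grid is None:
        grid = [(0.5, 1.0), (1.5, 2.0), (2.87, 3.22)]
    for v, a in grid:
        p = DDMParams(v=v, a=a, t0=0.0, lapse=0.0)
        dev = max_cdf_deviation(p, n_walks=n_walks, dt=dt, deadline=2.5,
                                seed=seed)
        report["oracle"].append({"v": v, "a": a, "max_cdf_dev": dev,
                                 "ok": bool(dev < 0.01)})
    report["passed"] = all(e["ok"] for e in report["normalization"]) and \
        all(e["ok"] for e in report["oracle"])
    return report


def max_cdf_deviation(params: DDMParams, n_walks: int, dt: float,
                      deadline: float, seed: int = 0) -> float:
    """Sup-distance between the Euler-simulated and density-implied
    sub-distribution CDFs P(choice, T <= t), pooled over both boundaries."""
    choice, rt = simulate_walks(DDMParams(params.v, params.a, params.t0, 0.0),
                                n_walks, dt=dt, deadline=deadline, seed=seed)
    tgrid = np.linspace(1e-4, deadline - params.t0, 600)
    up, lo = wfpt_pdf_grid(tgrid, params.v, params.a)
    cup = _cumtrapz(up, tgrid)
    clo = _cumtrapz(lo, tgrid)
    dev = 0.0
    tdec = rt - params.t0
    for cdf, code in ((cup, 1), (clo, 0)):
        sel = tdec[choice == code]
        emp = np.array([(sel <= t).sum() for t in tgrid], dtype=float) / n_walks
        dev = max(dev, float(np.max(np.abs(emp - cdf))))
    return dev


def _total_mass(params: DDMParams, horizon: float = 60.0, n_grid: int = 8192) -> float:
    """Numeric first-passage mass over both boundaries (quadrature on a
    log-spaced grid, which resolves the sharp early peak at small
    boundaries, plus the analytic tail)."""
    tgrid = np.concatenate([[0.0], np.geomspace(1e-7, horizon, n_grid)])
    up, lo = wfpt_pdf_grid(tgrid, params.v, params.a)
    mass = float(np.trapezoid(up + lo, tgrid))
    return mass + wfpt_survival(horizon, params.v, params.a)


def _cumtrapz(y, x):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def _as_seed(seed) -> int:
    return int(np.asarray(seed).item()) % (2**32 - 1)
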