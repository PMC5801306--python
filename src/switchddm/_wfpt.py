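"""Numba kernels for the two-boundary Wiener first-passage problem.

Everything here works on *decision time* (stimulus RT minus non-decision
time), with the starting point fixed midway between the boundaries
(w = 1/2) and unit diffusion noise (s = 1).  The first-passage density is
evaluated with the classical small-time / large-time series expansions,
choosing per evaluation whichever series needs fewer terms for a target
truncation error of ``SERIES_EPS``.

These kernels are private; the public surface lives in
:mod:`switchddm.ddm` and :mod:`switchddm.inference`.
"""

import math

import numpy as np
from numba import njit

# Series truncation tolerance for the density expansions.
SERIES_EPS = 1e-7

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _f1(u, w):
    """Density (lower boundary) at normalised time u for a=1, v=0, start w."""
    if u <= 0.0:
        return 0.0
    # number of terms needed by each expansion (truncation-error bounds)
    if 2.0 * math.sqrt(2.0 * math.pi * u) * SERIES_EPS < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * SERIES_EPS * math.sqrt(2.0 * math.pi * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    if math.pi * u * SERIES_EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * SERIES_EPS) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:
        K = int(math.ceil(ks))
        s = 0.0
        for k in range(-K, K + 1):
            x = w + 2.0 * k
            s += x * math.exp(-x * x / (2.0 * u))
        return s / math.sqrt(2.0 * math.pi * u * u * u)
    K = int(math.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * s


@njit(cache=True)
def wfpt_pdf(t_dec, upper, v, a):
    """First-passage density at decision time ``t_dec`` for boundary
    ``upper`` (True: correct/upper at a; False: error/lower at 0),
    drift v, separation a, start a/2, unit noise."""
    if t_dec <= 0.0 or a <= 0.0:
        return 0.0
    # upper-boundary passage == lower-boundary passage with drift flipped
    vv = -v if upper else v
    u = t_dec / (a * a)
    val = math.exp(-vv * a * 0.5 - vv * vv * t_dec / 2.0) * _f1(u, 0.5) / (a * a)
    if val < 0.0:
        val = 0.0
    return val


@njit(cache=True)
def _survival_one(T, vv, a):
    """Mass of the lower-boundary passage later than T, drift vv."""
    s = 0.0
    pref = math.pi / (a * a) * math.exp(-vv * a * 0.5)
    for k in range(1, 257):
        sk = math.sin(k * math.pi * 0.5)  # 1, 0, -1, 0, ...
        if sk == 0.0:
            continue
        lam = 0.5 * (vv * vv + k * k * math.pi * math.pi / (a * a))
        term = k * sk * math.exp(-lam * T) / lam
        s += term
        if abs(term) < SERIES_EPS * (abs(s) + 1e-12) and k > 4:
            break
    val = pref * s
    if val < 0.0:
        val = 0.0
    return val


@njit(cache=True)
def wfpt_survival(T, v, a):
    """P(decision time > T), both boundaries pooled, start a/2."""
    if T <= 0.0:
        return 1.0
    s = _survival_one(T, v, a) + _survival_one(T, -v, a)
    if s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def wfpt_pdf_grid(t_dec, v, a):
    """Vectorised density on a grid of decision times.

    Returns (upper, lower) density arrays."""
    n = t_dec.shape[0]
    up = np.empty(n)
    lo = np.empty(n)
    for i in range(n):
        up[i] = wfpt_pdf(t_dec[i], True, v, a)
        lo[i] = wfpt_pdf(t_dec[i], False, v, a)
    return up, lo


@njit(cache=True)
def loglik_trials(rt, correct, v, a, t0, lapse, deadline, censor):
    """Summed log-likelihood of resolved trials under the lapse mixture.

    rt : response times from stimulus onset (seconds), resolved trials only
    correct : int8 array, 1 = upper/correct, 0 = lower/error
    censor : renormalise the diffusion component to the mass that resolves
        before the deadline (trials beyond the deadline were omissions and
        are not in ``rt``).
    """
    n = rt.shape[0]
    if n == 0:
        return 0.0
    lz = 0.0
    if censor:
        Td = deadline - t0
        if Td <= 0.0:
            diff_mass = 0.0
        else:
            diff_mass = 1.0 - wfpt_survival(Td, v, a)
            if diff_mass < 0.0:
                diff_mass = 0.0
        Z = (1.0 - lapse) * diff_mass + lapse
        if Z <= 0.0:
            return -np.inf
        lz = math.log(Z)
    unif = lapse / (2.0 * deadline)
    total = 0.0
    for i in range(n):
        f = wfpt_pdf(rt[i] - t0, correct[i] == 1, v, a)
        like = (1.0 - lapse) * f + unif
        if like <= 0.0:
            return -np.inf
        total += math.log(like) - lz
    return total


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG (used by the Gibbs sweeps)."""
    np.random.seed(seed)


@njit(cache=True)
def euler_walks(v, a, t0, lapse, n, dt, deadline, seed, bridge=True):
    """Forward-simulate n trials of the random walk
    W(t+dt) = W(t) + v*dt + noise, noise ~ N(0, dt), from W(0) = a/2.

    With ``bridge`` (default) a Brownian-bridge test catches boundary
    crossings that occur *within* a step even when both endpoints lie
    inside the boundaries (crossing probability
    ``exp(-2 * d0 * d1 / dt)`` for endpoint distances d0, d1 to the
    boundary), removing the O(sqrt(dt)) late-absorption bias of the plain
    discrete-time check.

    Returns (choice, rt): choice 1 = upper/correct, 0 = lower/error,
    -1 = no response before the deadline (rt = nan).  Lapse trials draw a
    coin-flip choice and a uniform RT on (0, deadline]."""
    np.random.seed(seed)
    choice = np.empty(n, np.int8)
    rt = np.empty(n)
    max_steps = int((deadline - t0) / dt)
    sq = math.sqrt(dt)
    for i in range(n):
        if lapse > 0.0 and np.random.random() < lapse:
            choice[i] = 1 if np.random.random() < 0.5 else 0
            u = np.random.random() * deadline
            rt[i] = u if u > 0.0 else dt
            continue
        W = a / 2.0
        c = np.int8(-1)
        tdec = np.nan
        for step in range(1, max_steps + 1):
            Wn = W + v * dt + sq * np.random.standard_normal()
            if Wn >= a:
                c = np.int8(1)
                tdec = step * dt
                break
            if Wn <= 0.0:
                c = np.int8(0)
                tdec = step * dt
                break
            if bridge:
                # crossing probability is negligible (< ~1.5e-8) unless an
                # endpoint sits within a few step-widths of a boundary
                d_up = (a - W) * (a - Wn)
                d_lo = W * Wn
                if d_up < 9.0 * dt or d_lo < 9.0 * dt:
                    p_up = math.exp(-2.0 * d_up / dt)
                    p_lo = math.exp(-2.0 * d_lo / dt)
                    u = np.random.random()
                    if u < p_up:
                        c = np.int8(1)
                        tdec = step * dt - 0.5 * dt
                        break
                    if u < p_up + p_lo:
                        c = np.int8(0)
                        tdec = step * dt - 0.5 * dt
                        break
            W = Wn
        choice[i] = c
        rt[i] = t0 + tdec if c >= 0 else np.nan
    return choice, rt


@njit(cache=True)
def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd)


@njit(cache=True)
def subject_sweep(rt, correct, cstart, c_vidx, c_aidx,
                  v, a, t0_arr, cell_ll,
                  mu_v, sd_v, mu_a, sd_a, mu_t0, sd_t0,
                  sc_v, sc_a, sc_t0,
                  joint_lam, joint_acc, stat_n, stat_mean, stat_m2,
                  lapse, deadline, censor,
                  vlo, vhi, alo, ahi, t0lo, t0hi,
                  acc, trials_count):
    """One Metropolis-within-Gibbs sweep over a single subject's parameters.

    Trials are pre-sorted by joint (v-cell, a-cell) cell; ``cstart`` holds
    slice offsets per joint cell, ``c_vidx``/``c_aidx`` map each joint cell
    to its drift / boundary parameter index.  ``cell_ll`` caches the
    current per-cell log-likelihood and is updated in place.  ``acc``
    accumulates [v accepts, v tries, a accepts, a tries, t0 accepts,
    t0 tries, joint accepts, joint tries] for proposal-scale
    adaptation."""
    ncell = c_vidx.shape[0]
    nv = v.shape[0]
    na = a.shape[0]
    new_ll = np.empty(ncell)
    # drift-rate blocks
    for j in range(nv):
        acc[1] += 1.0
        prop = v[j] + sc_v[j] * np.random.standard_normal()
        if prop < vlo or prop > vhi:
            continue
        delta = _norm_logpdf(prop, mu_v[j], sd_v[j]) - _norm_logpdf(v[j], mu_v[j], sd_v[j])
        for c in range(ncell):
            if c_vidx[c] == j:
                new_ll[c] = loglik_trials(rt[cstart[c]:cstart[c + 1]],
                                          correct[cstart[c]:cstart[c + 1]],
                                          prop, a[c_aidx[c]], t0_arr[0],
                                          lapse, deadline, censor)
                delta += new_ll[c] - cell_ll[c]
        if math.log(np.random.random() + 1e-300) < delta:
            v[j] = prop
            for c in range(ncell):
                if c_vidx[c] == j:
                    cell_ll[c] = new_ll[c]
            acc[0] += 1.0
    # boundary blocks
    for j in range(na):
        acc[3] += 1.0
        prop = a[j] + sc_a[j] * np.random.standard_normal()
        if prop < alo or prop > ahi:
            continue
        delta = _norm_logpdf(prop, mu_a[j], sd_a[j]) - _norm_logpdf(a[j], mu_a[j], sd_a[j])
        for c in range(ncell):
            if c_aidx[c] == j:
                new_ll[c] = loglik_trials(rt[cstart[c]:cstart[c + 1]],
                                          correct[cstart[c]:cstart[c + 1]],
                                          v[c_vidx[c]], prop, t0_arr[0],
                                          lapse, deadline, censor)
                delta += new_ll[c] - cell_ll[c]
        if math.log(np.random.random() + 1e-300) < delta:
            a[j] = prop
            for c in range(ncell):
                if c_aidx[c] == j:
                    cell_ll[c] = new_ll[c]
            acc[2] += 1.0
    # joint drift-boundary moves: within a cell the posterior of (v, a)
    # is a correlated ridge (accuracy pins v*a), so scalar updates mix
    # slowly; propose both together.  Early in warmup the proposal uses
    # a fixed 0.9 correlation; once enough sweeps accumulate it switches
    # to the running per-cell covariance (adaptive Metropolis).
    for c in range(ncell):
        j = c_vidx[c]
        k = c_aidx[c]
        acc[7] += 1.0
        joint_acc[c, 1] += 1.0
        z1 = np.random.standard_normal()
        z2 = np.random.standard_normal()
        if stat_n[0] >= 25.0:
            denom = stat_n[0] - 1.0
            c11 = stat_m2[c, 0, 0] / denom + 1e-8
            c12 = stat_m2[c, 0, 1] / denom
            c22 = stat_m2[c, 1, 1] / denom + 1e-8
            l11 = math.sqrt(c11)
            l21 = c12 / l11
            rest = c22 - l21 * l21
            l22 = math.sqrt(rest) if rest > 1e-12 else 1e-6
            dv = joint_lam[c] * l11 * z1
            da = joint_lam[c] * (l21 * z1 + l22 * z2)
        else:
            dv = sc_v[j] * z1
            da = sc_a[k] * (0.9 * z1 + 0.43589 * z2)
        pv = v[j] + dv
        pa = a[k] + da
        if pv < vlo or pv > vhi or pa < alo or pa > ahi:
            continue
        delta = (_norm_logpdf(pv, mu_v[j], sd_v[j])
                 - _norm_logpdf(v[j], mu_v[j], sd_v[j])
                 + _norm_logpdf(pa, mu_a[k], sd_a[k])
                 - _norm_logpdf(a[k], mu_a[k], sd_a[k]))
        for m in range(ncell):
            if c_vidx[m] == j or c_aidx[m] == k:
                vm = pv if c_vidx[m] == j else v[c_vidx[m]]
                am = pa if c_aidx[m] == k else a[c_aidx[m]]
                new_ll[m] = loglik_trials(rt[cstart[m]:cstart[m + 1]],
                                          correct[cstart[m]:cstart[m + 1]],
                                          vm, am, t0_arr[0],
                                          lapse, deadline, censor)
                delta += new_ll[m] - cell_ll[m]
        if math.log(np.random.random() + 1e-300) < delta:
            v[j] = pv
            a[k] = pa
            for m in range(ncell):
                if c_vidx[m] == j or c_aidx[m] == k:
                    cell_ll[m] = new_ll[m]
            acc[6] += 1.0
            joint_acc[c, 0] += 1.0
    # running per-cell (v, a) moments for the adaptive joint proposal
    stat_n[0] += 1.0
    for c in range(ncell):
        x0 = v[c_vidx[c]]
        x1 = a[c_aidx[c]]
        d0 = x0 - stat_mean[c, 0]
        d1 = x1 - stat_mean[c, 1]
        stat_mean[c, 0] += d0 / stat_n[0]
        stat_mean[c, 1] += d1 / stat_n[0]
        e0 = x0 - stat_mean[c, 0]
        e1 = x1 - stat_mean[c, 1]
        stat_m2[c, 0, 0] += d0 * e0
        stat_m2[c, 0, 1] += d0 * e1
        stat_m2[c, 1, 0] += d1 * e0
        stat_m2[c, 1, 1] += d1 * e1
    # shared non-decision time
    acc[5] += 1.0
    prop = t0_arr[0] + sc_t0[0] * np.random.standard_normal()
    if t0lo <= prop <= t0hi:
        delta = _norm_logpdf(prop, mu_t0[0], sd_t0[0]) - _norm_logpdf(t0_arr[0], mu_t0[0], sd_t0[0])
        for c in range(ncell):
            new_ll[c] = loglik_trials(rt[cstart[c]:cstart[c + 1]],
                                      correct[cstart[c]:cstart[c + 1]],
                                      v[c_vidx[c]], a[c_aidx[c]], prop,
                                      lapse, deadline, censor)
            delta += new_ll[c] - cell_ll[c]
        if math.log(np.random.random() + 1e-300) < delta:
            t0_arr[0] = prop
            for c in range(ncell):
                cell_ll[c] = new_ll[c]
            acc[4] += 1.0
    return 0
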