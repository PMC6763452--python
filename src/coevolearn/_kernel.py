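"""Numba-jitted Monte Carlo driver.

Implements the identical elementary step as :mod:`coevolearn.engine` on the
raw arrays of a :class:`~coevolearn.core.World`, at the speed needed for
lattice sweeps (L = 100, tens of thousands of MC steps).  Randomness uses
numba's thread-local numpy legacy generator, seeded once per kernel call, so
a (seed, initial world, params) triple gives a bit-identical trajectory.

Draw order per elementary update (matching the reference engine):
focal site -> neighbour index -> acceptance uniform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_steps"]

# Rule codes: 0 = both strategies evolve w, 1 = cooperators only,
# 2 = defectors only.  Gating / payoff basis: 0 = post-adoption,
# 1 = pre-adoption.  Comparison set: 0 = all neighbours, 1 = same
# strategy, 2 = different.


@njit(cache=True, inline="always")
def _site_payoff(strat, neigh, deg, i, b):
    s = strat[i]
    p = 0.0
    for j in range(deg[i]):
        t = strat[neigh[i, j]]
        if s == 1:
            if t == 1:
                p += 1.0
        else:
            if t == 1:
                p += b
    return p


@njit(cache=True)
def run_steps(
    strat,
    w,
    neigh,
    deg,
    b,
    K,
    d,
    w_min,
    w_max,
    rule,
    gating,
    pbasis,
    comp,
    n_steps,
    record_every,
    avg_window,
    early_stop,
    seed,
):
    """Advance ``n_steps`` full MC steps in place.

    Returns ``(rec_t, rec_fc, rec_wc, rec_wd, n_rec, absorbed_step,
    stationary_fc, no_comparison_count)`` where the ``rec_*`` arrays are
    valid up to ``n_rec`` entries, ``absorbed_step`` is -1 when the strategy
    dynamics never absorbed, and ``stationary_fc`` is the mean cooperation
    density over the trailing ``avg_window`` steps (or the absorbed value).
    """
    np.random.seed(seed)
    n = strat.shape[0]
    kmax = neigh.shape[1]
    pn = np.empty(kmax)

    n_rec_max = n_steps // record_every + 2
    rec_t = np.empty(n_rec_max, np.int64)
    rec_fc = np.empty(n_rec_max)
    rec_wc = np.empty(n_rec_max)
    rec_wd = np.empty(n_rec_max)

    nc = 0
    for i in range(n):
        nc += strat[i]

    n_rec = 0
    rec_t[n_rec] = 0
    rec_fc[n_rec] = nc / n
    wc, wd = _mean_w(strat, w, n)
    rec_wc[n_rec] = wc
    rec_wd[n_rec] = wd
    n_rec += 1

    absorbed_step = -1
    no_comparison = 0
    fc_tail_sum = 0.0
    fc_tail_n = 0
    tail_start = n_steps - avg_window  # steps t > tail_start enter the average

    for t in range(1, n_steps + 1):
        for _ in range(n):
            x = np.random.randint(0, n)
            kx = deg[x]
            px = _site_payoff(strat, neigh, deg, x, b)
            for j in range(kx):
                pn[j] = _site_payoff(strat, neigh, deg, neigh[x, j], b)
            jy = np.random.randint(0, kx)
            y = neigh[x, jy]

            arg = (px - pn[jy]) / K
            if arg > 700.0:
                arg = 700.0
            elif arg < -700.0:
                arg = -700.0
            prob = w[x] / (1.0 + np.exp(arg))

            sx_old = strat[x]
            if np.random.random() < prob:
                sy = strat[y]
                if sy != sx_old:
                    strat[x] = sy
                    nc += sy - sx_old

            if gating == 0:
                gs = strat[x]
            else:
                gs = sx_old
            enabled = (
                rule == 0 or (rule == 1 and gs == 1) or (rule == 2 and gs == 0)
            )
            if enabled:
                px_cmp = px
                if pbasis == 0 and strat[x] != sx_old:
                    # the flip changed the focal and neighbour payoffs
                    px_cmp = _site_payoff(strat, neigh, deg, x, b)
                    for j in range(kx):
                        pn[j] = _site_payoff(strat, neigh, deg, neigh[x, j], b)
                tot = 0.0
                cnt = 0
                if comp == 0:
                    for j in range(kx):
                        tot += pn[j]
                    cnt = kx
                else:
                    for j in range(kx):
                        sn = strat[neigh[x, j]]
                        if (comp == 1 and sn == gs) or (comp == 2 and sn != gs):
                            tot += pn[j]
                            cnt += 1
                if cnt > 0:
                    pbar = tot / cnt
                    if px_cmp < pbar:
                        wn = w[x] + d
                        if wn > w_max:
                            wn = w_max
                        w[x] = wn
                    else:
                        wn = w[x] - d
                        if wn < w_min:
                            wn = w_min
                        w[x] = wn
                else:
                    no_comparison += 1

        if t > tail_start:
            fc_tail_sum += nc / n
            fc_tail_n += 1

        if t % record_every == 0:
            rec_t[n_rec] = t
            rec_fc[n_rec] = nc / n
            wc, wd = _mean_w(strat, w, n)
            rec_wc[n_rec] = wc
            rec_wd[n_rec] = wd
            n_rec += 1

        if early_stop and (nc == 0 or nc == n):
            absorbed_step = t
            if t % record_every != 0:
                rec_t[n_rec] = t
                rec_fc[n_rec] = nc / n
                wc, wd = _mean_w(strat, w, n)
                rec_wc[n_rec] = wc
                rec_wd[n_rec] = wd
                n_rec += 1
            break

    if absorbed_step >= 0:
        stationary_fc = nc / n
    elif fc_tail_n > 0:
        stationary_fc = fc_tail_sum / fc_tail_n
    else:
        stationary_fc = nc / n

    return (
        rec_t,
        rec_fc,
        rec_wc,
        rec_wd,
        n_rec,
        absorbed_step,
        stationary_fc,
        no_comparison,
    )


@njit(cache=True, inline="always")
def _mean_w(strat, w, n):
    """Mean learning ability among cooperators and defectors (nan if absent)."""
    sc = 0.0
    sd = 0.0
    cc = 0
    cd = 0
    for i in range(n):
        if strat[i] == 1:
            sc += w[i]
            cc += 1
        else:
            sd += w[i]
            cd += 1
    wc = sc / cc if cc > 0 else np.nan
    wd = sd / cd if cd > 0 else np.nan
    return wc, wd
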