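"""Numba batch kernel for the structured coalescent.

Simulates genealogies backwards in time under the two-population
isolation-with-migration history and accumulates, per replicate, the
summed branch length subtending (i, j) leaves of each population — the
branch-category matrix whose Monte-Carlo mean (divided by 2) is the
expected joint SFS per unit theta.  Optionally drops infinite-sites
mutations on the fly (Poisson per branch) to produce SFS-level datasets,
with an external-branch rate multiplier emulating a low-recombination
singleton excess.

Time is in units of 2 N_ANC generations; the pairwise coalescence rate
in a population of relative size nu is 1/nu; per-lineage backward
migration rates are the scaled 2 N_ANC m of the receiving-forward
direction.  The European size follows nu_eu * exp(-beta t) backwards
from the present, with waiting times drawn by analytic inversion of the
cumulative coalescence intensity (exact, no time stepping).

A lineage's leaf-count category never changes between the coalescences
that create and absorb it, so branch lengths are finalized per lineage
(birth-to-death), not per event interval.

This kernel intentionally mirrors the pure-Python genealogy simulator in
:mod:`demosfs.simulate`; the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1.0e30


@njit(cache=True)
def _exp_wait(rate):
    if rate <= 0.0:
        return _BIG
    return -np.log(np.random.random()) / rate


@njit(cache=True)
def _eu_coal_wait(k_eu, t, nu_eu, beta):
    """Waiting time from t for a coalescence in the exponentially growing
    European population, by inversion of the cumulative hazard."""
    if k_eu < 2:
        return _BIG
    c = 0.5 * k_eu * (k_eu - 1)
    e = -np.log(np.random.random())
    if beta == 0.0:
        return e * nu_eu / c
    arg = np.exp(beta * t) + e * nu_eu * beta / c
    if arg <= 0.0:
        return _BIG  # shrinking intensity never accumulates enough hazard
    s = np.log(arg) / beta - t
    if s <= 0.0:
        s = 1e-300
    return s


@njit(cache=True)
def _pick_two(pop, k, target_pop, kp):
    """Indices of two distinct uniformly chosen active lineages in target_pop."""
    a = np.random.randint(kp)
    b = np.random.randint(kp - 1)
    if b >= a:
        b += 1
    ia = -1
    ib = -1
    seen = 0
    for i in range(k):
        if pop[i] == target_pop:
            if seen == a:
                ia = i
            if seen == b:
                ib = i
            seen += 1
    return ia, ib


@njit(cache=True)
def _pick_one(pop, k, target_pop, kp):
    a = np.random.randint(kp)
    seen = 0
    for i in range(k):
        if pop[i] == target_pop:
            if seen == a:
                return i
            seen += 1
    return -1


@njit(cache=True)
def _finalize(i, t, c1, c2, t_birth, theta_locus, inflation_f, t_loc, sfs_counts):
    """Close the branch above lineage slot i at time t: record its length
    and, when mutating, its Poisson mutation count."""
    ell = t - t_birth[i]
    a = c1[i]
    b = c2[i]
    t_loc[a, b] += ell
    if theta_locus > 0.0 and ell > 0.0:
        lam = 0.5 * theta_locus * ell
        if a + b == 1:
            lam *= inflation_f
        m = np.random.poisson(lam)
        if m > 0:
            sfs_counts[a, b] += m


@njit(cache=True)
def simulate_batch(
    n1,
    n2,
    nu_af,
    nu_bot,
    nu_eu,
    t_exp,
    t_split,
    m_back_eu,  # per-lineage backward rate for EU lineages (= M_AtoE)
    m_back_af,  # per-lineage backward rate for AF lineages (= M_EtoA)
    t_mig,  # migration active only for t < t_mig (pass t_split when ungated)
    n_reps,
    seed,
    theta_locus,  # if > 0, drop mutations and fill sfs_counts
    inflation_f,  # external-branch mutation-rate multiplier
    len_sum,  # (n1+1, n2+1) out: sum of branch-category lengths
    len_sumsq,  # (n1+1, n2+1) out: sum of squares (for standard errors)
    sfs_counts,  # (n1+1, n2+1) int64 out: mutation counts
):
    np.random.seed(seed)
    n = n1 + n2
    pop = np.empty(n, dtype=np.int8)
    c1 = np.empty(n, dtype=np.int64)
    c2 = np.empty(n, dtype=np.int64)
    t_birth = np.empty(n, dtype=np.float64)
    t_loc = np.empty((n1 + 1, n2 + 1), dtype=np.float64)
    if nu_eu != nu_bot:
        beta = np.log(nu_eu / nu_bot) / t_split
    else:
        beta = 0.0

    for _rep in range(n_reps):
        k = n
        for i in range(n1):
            pop[i] = 0
            c1[i] = 1
            c2[i] = 0
            t_birth[i] = 0.0
        for i in range(n1, n):
            pop[i] = 1
            c1[i] = 0
            c2[i] = 1
            t_birth[i] = 0.0
        t_loc[:, :] = 0.0
        t = 0.0
        k_af = n1
        k_eu = n2

        while k > 1:
            if t < t_split:
                size_af = nu_af
                mig_on = t < t_mig
                boundary = t_mig if mig_on and t_mig < t_split else t_split
            elif t < t_exp:
                size_af = nu_af
                mig_on = False
                boundary = t_exp
            else:
                size_af = 1.0
                mig_on = False
                boundary = _BIG

            w_caf = _exp_wait(0.5 * k_af * (k_af - 1) / size_af)
            if t < t_split:
                w_ceu = _eu_coal_wait(k_eu, t, nu_eu, beta)
            else:
                w_ceu = _BIG
            if mig_on:
                w_maf = _exp_wait(k_af * m_back_af)
                w_meu = _exp_wait(k_eu * m_back_eu)
            else:
                w_maf = _BIG
                w_meu = _BIG

            w = w_caf
            ev = 0  # 0: coal AF, 1: coal EU, 2: AF->EU migration, 3: EU->AF
            if w_ceu < w:
                w = w_ceu
                ev = 1
            if w_maf < w:
                w = w_maf
                ev = 2
            if w_meu < w:
                w = w_meu
                ev = 3

            if t + w >= boundary:
                t = boundary
                if boundary == t_split:
                    for i in range(k):
                        pop[i] = 0
                    k_af = k
                    k_eu = 0
                continue

            t = t + w
            if ev == 0 or ev == 1:
                p = 0 if ev == 0 else 1
                kp = k_af if ev == 0 else k_eu
                ia, ib = _pick_two(pop, k, p, kp)
                _finalize(ia, t, c1, c2, t_birth, theta_locus, inflation_f,
                          t_loc, sfs_counts)
                _finalize(ib, t, c1, c2, t_birth, theta_locus, inflation_f,
                          t_loc, sfs_counts)
                c1[ia] += c1[ib]
                c2[ia] += c2[ib]
                t_birth[ia] = t
                # swap-remove ib
                k -= 1
                pop[ib] = pop[k]
                c1[ib] = c1[k]
                c2[ib] = c2[k]
                t_birth[ib] = t_birth[k]
                if p == 0:
                    k_af -= 1
                else:
                    k_eu -= 1
            elif ev == 2:
                i = _pick_one(pop, k, 0, k_af)
                pop[i] = 1
                k_af -= 1
                k_eu += 1
            else:
                i = _pick_one(pop, k, 1, k_eu)
                pop[i] = 0
                k_af += 1
                k_eu -= 1

        for a in range(n1 + 1):
            for b in range(n2 + 1):
                x = t_loc[a, b]
                len_sum[a, b] += x
                len_sumsq[a, b] += x * x
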