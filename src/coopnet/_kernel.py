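"""Numba-jitted inner loops for ministep simulation.

The kernel mirrors :func:`coopnet.effects.contribution_matrix` exactly
(the NumPy version is the reference the tests check against) but runs the
whole between-wave chain of ministeps without returning to Python.

Opportunity process: each actor receives change opportunities at rate
``lam`` while present; simulation draws the total event count from
Poisson(lam * n), assigns each event a uniform time on [0, 1] and a
uniform actor, and skips events falling outside the actor's presence
window — an exact thinning of the per-actor Poisson processes.

Random draws per event, in fixed order: event times (all up front, then
sorted), then per event one draw for the actor and one for the option.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# kind codes — keep identical to coopnet.effects
_K_OUTDEGREE = 0
_K_RECIPROCITY = 1
_K_TRANS_TRIP = 2
_K_THREE_CYCLES = 3
_K_IN_POP = 4
_K_OUT_ACT = 5
_K_IN_ACT = 6
_K_ALTER = 7
_K_EGO = 8
_K_SAME = 9
_K_ABS_DIFF = 10
_K_DYADIC = 11
_K_INTERACTION = 12


@njit(cache=True)
def _fill_contributions(X, kinds, cov_idx, parent_idx, V, W, i, indeg, D):
    """Fill D (n_eff, n) with signed change statistics for ego i."""
    n = X.shape[0]
    n_eff = kinds.shape[0]
    outdeg_i = 0.0
    indeg_i = 0.0
    for j in range(n):
        outdeg_i += X[i, j]
        indeg_i += X[j, i]
    twopath = np.zeros(n)
    j_to_alters = np.zeros(n)
    cycles = np.zeros(n)
    for h in range(n):
        if X[i, h]:
            for j in range(n):
                twopath[j] += X[h, j]
                j_to_alters[j] += X[j, h]
        if X[h, i]:
            for j in range(n):
                cycles[j] += X[j, h]
    for k in range(n_eff):
        kind = kinds[k]
        ci = cov_idx[k]
        if kind == _K_INTERACTION:
            f = V[ci, i]
            p = parent_idx[k]
            for j in range(n):
                D[k, j] = f * D[p, j]
        else:
            for j in range(n):
                sign = 1.0 - 2.0 * X[i, j]
                if kind == _K_OUTDEGREE:
                    c = 1.0
                elif kind == _K_RECIPROCITY:
                    c = X[j, i]
                elif kind == _K_TRANS_TRIP:
                    c = twopath[j] + j_to_alters[j]
                elif kind == _K_THREE_CYCLES:
                    c = cycles[j]
                elif kind == _K_IN_POP:
                    c = indeg[j] - X[i, j] + 1.0
                elif kind == _K_OUT_ACT:
                    c = 2.0 * (outdeg_i - X[i, j]) + 1.0
                elif kind == _K_IN_ACT:
                    c = indeg_i
                elif kind == _K_ALTER:
                    c = V[ci, j]
                elif kind == _K_EGO:
                    c = V[ci, i]
                elif kind == _K_SAME:
                    c = 1.0 if V[ci, j] == V[ci, i] else 0.0
                elif kind == _K_ABS_DIFF:
                    c = abs(V[ci, j] - V[ci, i])
                else:  # dyadic
                    c = W[ci, i, j]
                D[k, j] = sign * c
        D[k, i] = 0.0


@njit(cache=True)
def simulate_chain(
    X,
    X0,
    kinds,
    cov_idx,
    parent_idx,
    V,
    W,
    beta,
    lam,
    entry,
    exit_,
    seed,
    conditional,
    target_hamming,
    fixed_steps,
    record,
):
    """Run one between-wave chain of ministeps in place on X.

    Returns (score, n_opportunities, hamming, rec_actor, rec_alter,
    rec_time). ``score`` is the path score: entry 0 w.r.t. log-rate,
    entries 1.. w.r.t. each beta — used for derivative estimation.
    If ``conditional`` the chain stops once the Hamming distance to ``X0``
    reaches ``target_hamming``; if ``fixed_steps >= 0`` exactly that many
    opportunities occur (overrides the Poisson draw).
    """
    np.random.seed(seed)
    n = X.shape[0]
    n_eff = kinds.shape[0]

    if fixed_steps >= 0:
        M = fixed_steps
    else:
        M = np.random.poisson(lam * n)
    times = np.sort(np.random.random(M))

    indeg = np.zeros(n)
    for i in range(n):
        for j in range(n):
            indeg[j] += X[i, j]

    hamming = 0
    for i in range(n):
        for j in range(n):
            if X[i, j] != X0[i, j]:
                hamming += 1

    score = np.zeros(n_eff + 1)
    D = np.zeros((n_eff, n))
    gains = np.zeros(n)
    probs = np.zeros(n)

    cap = M if record else 0
    rec_actor = np.full(cap, -1, dtype=np.int64)
    rec_alter = np.full(cap, -1, dtype=np.int64)
    rec_time = np.zeros(cap)
    rec_gains = np.zeros((cap, n))

    m_eff = 0  # opportunities given to present actors
    t_total = 0.0  # total presence time (for the rate score)
    for i in range(n):
        t_total += exit_[i] - entry[i]

    for step in range(M):
        t = times[step]
        i = int(np.random.random() * n)
        if i >= n:
            i = n - 1
        actor_draw = np.random.random()  # consumed even when skipped, for replay
        if t < entry[i] or t > exit_[i]:
            continue
        m_eff += 1
        _fill_contributions(X, kinds, cov_idx, parent_idx, V, W, i, indeg, D)
        gmax = 0.0
        for j in range(n):
            g = 0.0
            if j != i and entry[j] <= t <= exit_[j]:
                for k in range(n_eff):
                    g += beta[k] * D[k, j]
            elif j != i:
                g = -np.inf  # absent alters are not options
            gains[j] = g
            if g > gmax:
                gmax = g
        z = 0.0
        for j in range(n):
            if gains[j] == -np.inf:
                probs[j] = 0.0
            else:
                probs[j] = np.exp(gains[j] - gmax)
            z += probs[j]
        r = actor_draw * z
        chosen = i
        acc = 0.0
        for j in range(n):
            acc += probs[j]
            if r < acc:
                chosen = j
                break
        # score accumulation: Delta(chosen) - E[Delta]
        for k in range(n_eff):
            e = 0.0
            for j in range(n):
                e += probs[j] / z * D[k, j]
            score[k + 1] += D[k, chosen] - e
        if record:
            rec_actor[step] = i
            rec_alter[step] = chosen
            rec_time[step] = t
            for j in range(n):
                rec_gains[step, j] = gains[j]
        if chosen != i:
            old = X[i, chosen]
            if old:
                X[i, chosen] = 0
                indeg[chosen] -= 1.0
                if X0[i, chosen] == 1:
                    hamming += 1
                else:
                    hamming -= 1
            else:
                X[i, chosen] = 1
                indeg[chosen] += 1.0
                if X0[i, chosen] == 0:
                    hamming += 1
                else:
                    hamming -= 1
            if conditional and hamming >= target_hamming:
                break

    score[0] = m_eff - lam * t_total  # d log P / d log(lam)
    return score, m_eff, hamming, rec_actor, rec_alter, rec_time, rec_gains
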