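"""Numba-compiled numerical kernels shared by the engines.

All kernels operate on the flat compiled form of a reaction network: a
``(n_reactions, 2)`` array of reactant species indices (-1 marks an empty
slot; a repeated index marks homodimerization), a dense stoichiometry
change matrix and a rate vector.  Every reaction in the model has at most
two reactant molecules, which the kernels exploit; the dense
stoichiometry is sparsified internally so the per-step cost scales with
the number of species actually changed by each reaction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by the fixed-step integrators
OK = 0
OVERFLOW = 1

_OVERFLOW_GUARD = 1e12


@njit(cache=True)
def _sparsify(stoich):
    """Per-reaction lists of (species index, net change) from dense stoich."""
    n_r, n_s = stoich.shape
    counts = np.zeros(n_r, dtype=np.int64)
    for r in range(n_r):
        for s in range(n_s):
            if stoich[r, s] != 0.0:
                counts[r] += 1
    width = counts.max() if n_r else 0
    idx = np.zeros((n_r, width), dtype=np.int64)
    val = np.zeros((n_r, width), dtype=np.float64)
    for r in range(n_r):
        c = 0
        for s in range(n_s):
            if stoich[r, s] != 0.0:
                idx[r, c] = s
                val[r, c] = stoich[r, s]
                c += 1
    return idx, val, counts


@njit(cache=True)
def mass_action_rhs(y, pairs, stoich, k):
    """Deterministic mass-action derivative: flux_r = k_r * prod(y[reactants])."""
    n_r = pairs.shape[0]
    dy = np.zeros(y.shape[0])
    for r in range(n_r):
        flux = k[r]
        i1, i2 = pairs[r, 0], pairs[r, 1]
        if i1 >= 0:
            flux *= y[i1]
        if i2 >= 0:
            flux *= y[i2]
        if flux != 0.0:
            for s in range(y.shape[0]):
                if stoich[r, s] != 0.0:
                    dy[s] += stoich[r, s] * flux
    return dy


@njit(cache=True)
def propensity_vector(x, pairs, stoich, k):
    """Stochastic propensities; homodimerization uses x*(x-1)."""
    n_r = pairs.shape[0]
    a = np.empty(n_r)
    for r in range(n_r):
        prop = k[r]
        i1, i2 = pairs[r, 0], pairs[r, 1]
        if i1 >= 0:
            prop *= x[i1]
        if i2 >= 0:
            if i2 == i1:
                prop *= x[i2] - 1.0
            else:
                prop *= x[i2]
        a[r] = prop if prop > 0.0 else 0.0
    return a


@njit(cache=True, inline="always")
def _euler_step(y, flux, pairs, idx, val, counts, k, dt):
    n_r = pairs.shape[0]
    for r in range(n_r):
        f = k[r]
        i1, i2 = pairs[r, 0], pairs[r, 1]
        if i1 >= 0:
            f *= y[i1]
        if i2 >= 0:
            f *= y[i2]
        flux[r] = f
    for r in range(n_r):
        f = dt * flux[r]
        if f != 0.0:
            for c in range(counts[r]):
                y[idx[r, c]] += val[r, c] * f


@njit(cache=True, inline="always")
def _rhs_inplace(y, pairs, idx, val, counts, k, dy):
    for s in range(dy.shape[0]):
        dy[s] = 0.0
    for r in range(pairs.shape[0]):
        f = k[r]
        i1, i2 = pairs[r, 0], pairs[r, 1]
        if i1 >= 0:
            f *= y[i1]
        if i2 >= 0:
            f *= y[i2]
        if f != 0.0:
            for c in range(counts[r]):
                dy[idx[r, c]] += val[r, c] * f


@njit(cache=True, inline="always")
def _rk4_step_inplace(y, pairs, idx, val, counts, k, dt, k1, k2, k3, k4, yt):
    n_s = y.shape[0]
    _rhs_inplace(y, pairs, idx, val, counts, k, k1)
    for s in range(n_s):
        yt[s] = y[s] + 0.5 * dt * k1[s]
    _rhs_inplace(yt, pairs, idx, val, counts, k, k2)
    for s in range(n_s):
        yt[s] = y[s] + 0.5 * dt * k2[s]
    _rhs_inplace(yt, pairs, idx, val, counts, k, k3)
    for s in range(n_s):
        yt[s] = y[s] + dt * k3[s]
    _rhs_inplace(yt, pairs, idx, val, counts, k, k4)
    for s in range(n_s):
        y[s] += (dt / 6.0) * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])


@njit(cache=True)
def euler_record(y, pairs, stoich, k, dt, n_steps, stride):
    """Forward Euler with strided state recording.

    Negative excursions from overshoot are clipped to zero (counted);
    any state magnitude beyond the overflow guard aborts with a status.
    Returns (recorded states, n recorded, clip count, status, steps done).
    """
    n_s = y.shape[0]
    idx, val, counts = _sparsify(stoich)
    flux = np.empty(pairs.shape[0])
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec + 1, n_s))
    out[0] = y
    rec = 1
    n_clip = 0
    for step in range(1, n_steps + 1):
        _euler_step(y, flux, pairs, idx, val, counts, k, dt)
        for s in range(n_s):
            if y[s] < 0.0:
                y[s] = 0.0
                n_clip += 1
            elif y[s] > _OVERFLOW_GUARD:
                return out, rec, n_clip, OVERFLOW, step
        if step % stride == 0:
            out[rec] = y
            rec += 1
    if (n_steps % stride) != 0:
        out[rec] = y
        rec += 1
    return out, rec, n_clip, OK, n_steps


@njit(cache=True)
def rk4_record(y, pairs, stoich, k, dt, n_steps, stride):
    """Classical fourth-order Runge-Kutta, same contract as euler_record."""
    n_s = y.shape[0]
    idx, val, counts = _sparsify(stoich)
    k1 = np.empty(n_s); k2 = np.empty(n_s); k3 = np.empty(n_s); k4 = np.empty(n_s)
    yt = np.empty(n_s)
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec + 1, n_s))
    out[0] = y
    rec = 1
    n_clip = 0
    for step in range(1, n_steps + 1):
        _rk4_step_inplace(y, pairs, idx, val, counts, k, dt, k1, k2, k3, k4, yt)
        for s in range(n_s):
            if y[s] < 0.0:
                y[s] = 0.0
                n_clip += 1
            elif y[s] > _OVERFLOW_GUARD:
                return out, rec, n_clip, OVERFLOW, step
        if step % stride == 0:
            out[rec] = y
            rec += 1
    if (n_steps % stride) != 0:
        out[rec] = y
        rec += 1
    return out, rec, n_clip, OK, n_steps


@njit(cache=True)
def fixed_step_window(y, pairs, stoich, k, dt, n_steps, use_rk4):
    """One convergence-assessment window of a fixed-step scheme.

    Tracks the per-species min/max envelope over the window so the caller
    can evaluate the windowed convergence residual max_s (max - min).
    Returns (y, mins, maxs, clip count, status, steps done).
    """
    n_s = y.shape[0]
    idx, val, counts = _sparsify(stoich)
    flux = np.empty(pairs.shape[0])
    k1 = np.empty(n_s); k2 = np.empty(n_s); k3 = np.empty(n_s); k4 = np.empty(n_s)
    yt = np.empty(n_s)
    mins = y.copy()
    maxs = y.copy()
    n_clip = 0
    for step in range(1, n_steps + 1):
        if use_rk4:
            _rk4_step_inplace(y, pairs, idx, val, counts, k, dt, k1, k2, k3, k4, yt)
        else:
            _euler_step(y, flux, pairs, idx, val, counts, k, dt)
        for s in range(n_s):
            if y[s] < 0.0:
                y[s] = 0.0
                n_clip += 1
            elif y[s] > _OVERFLOW_GUARD:
                return y, mins, maxs, n_clip, OVERFLOW, step
            if y[s] < mins[s]:
                mins[s] = y[s]
            if y[s] > maxs[s]:
                maxs[s] = y[s]
    return y, mins, maxs, n_clip, OK, n_steps


@njit(cache=True)
def gillespie_sampled(x0, pairs, stoich, k, t_max, sample_dt, seed):
    """Gillespie direct method, state sampled on a uniform time grid.

    Returns (samples, n_events, t_absorbed) where ``samples[i]`` is the
    state at time ``i * sample_dt`` (the state holds between events, so
    grid samples are exact) and ``t_absorbed`` is the time at which total
    propensity hit zero, or -1.0 if the system stayed active to t_max.
    """
    np.random.seed(seed)
    n_s = x0.shape[0]
    n_r = pairs.shape[0]
    idx, val, counts = _sparsify(stoich)
    n_samples = int(t_max / sample_dt) + 1
    samples = np.empty((n_samples, n_s))
    x = x0.astype(np.float64)
    t = 0.0
    next_sample = 0
    n_events = 0
    t_absorbed = -1.0
    a = np.empty(n_r)
    while True:
        a0 = 0.0
        for r in range(n_r):
            prop = k[r]
            i1, i2 = pairs[r, 0], pairs[r, 1]
            if i1 >= 0:
                prop *= x[i1]
            if i2 >= 0:
                if i2 == i1:
                    prop *= x[i2] - 1.0
                else:
                    prop *= x[i2]
            if prop < 0.0:
                prop = 0.0
            a[r] = prop
            a0 += prop
        if a0 <= 0.0:
            t_absorbed = t
            t_next = t_max + sample_dt  # state frozen to the end
        else:
            t_next = t - np.log(np.random.random()) / a0
        # emit samples for every grid time passed before the next event
        while next_sample * sample_dt < t_next and next_sample < n_samples:
            samples[next_sample] = x
            next_sample += 1
        if t_next > t_max or a0 <= 0.0:
            break
        # pick the reaction channel
        target = np.random.random() * a0
        acc = 0.0
        chosen = n_r - 1
        for r in range(n_r):
            acc += a[r]
            if target < acc:
                chosen = r
                break
        for c in range(counts[chosen]):
            x[idx[chosen, c]] += val[chosen, c]
        t = t_next
        n_events += 1
    while next_sample < n_samples:
        samples[next_sample] = x
        next_sample += 1
    return samples, n_events, t_absorbed
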