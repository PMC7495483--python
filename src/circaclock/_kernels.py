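"""Compiled cores for the exact stochastic simulation algorithm.

The Gillespie direct method is implemented with an inline xoshiro256**
generator (seeded through splitmix64, so per-trajectory streams are cheap,
reproducible and order-independent), incremental propensity updates driven by
a reaction dependency table, and exact handling of the square-wave light
switch: a waiting time drawn across a light boundary is truncated at the
boundary, propensities are re-evaluated under the new ``s(t)`` and the
exponential clock is redrawn (valid by memorylessness).

Mass-action propensities up to order 8 are supported; repeated reactant or
catalyst members use falling factorials through the per-slot offset table.
Light-gated channels carry an effective rate that is rewritten only when the
switch changes, keeping the per-event path branch-light.
"""

import numpy as np
from numba import njit

#: Status codes returned by the kernels.
OK = 0
MAX_EVENTS = 1

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _splitmix64(state):
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return state, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rotl(x, k):
    return ((x << np.uint64(k)) | (x >> np.uint64(64 - k))) & _MASK


@njit(cache=True)
def _seed_state(seed):
    s = np.empty(4, dtype=np.uint64)
    state = np.uint64(seed)
    for i in range(4):
        state, z = _splitmix64(state)
        s[i] = z
    return s


@njit(cache=True, inline="always")
def _next_u64(s):
    result = (_rotl((s[1] * np.uint64(5)) & _MASK, 7) * np.uint64(9)) & _MASK
    t = (s[1] << np.uint64(17)) & _MASK
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], 45)
    return result


@njit(cache=True, inline="always")
def _uniform(s):
    # 53-bit mantissa in [0, 1)
    return (_next_u64(s) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always", fastmath=True)
def _propensity(j, x, eff_rates, prop_idx, prop_off, n_slots):
    a = eff_rates[j]
    k = n_slots[j]
    if k == 0:
        return a
    i0 = prop_idx[j, 0]
    v = x[i0]
    if v <= 0:
        return 0.0
    a *= v
    if k == 1:
        return a
    for q in range(1, k):
        m = x[prop_idx[j, q]] - prop_off[j, q]
        if m <= 0:
            return 0.0
        a *= m
    return a


@njit(cache=True, fastmath=True)
def _all_propensities(x, eff_rates, prop_idx, prop_off, n_slots, a):
    a0 = 0.0
    for j in range(eff_rates.size):
        a[j] = _propensity(j, x, eff_rates, prop_idx, prop_off, n_slots)
        a0 += a[j]
    return a0


@njit(cache=True, inline="always")
def _set_light(rates, uses_light, s_cur, eff_rates):
    for j in range(rates.size):
        if uses_light[j]:
            eff_rates[j] = rates[j] * s_cur
        else:
            eff_rates[j] = rates[j]


@njit(cache=True, fastmath=True)
def ssa_grid(rates, uses_light, prop_idx, prop_off, st_sp, st_dl, dep,
             x0, sw_t, sw_s, s_init, t_grid, seed, max_events):
    """Direct-method trajectory recorded on a uniform grid.

    Returns ``(out, n_events, status)`` where ``out[k, i]`` is the count of
    species ``i`` after the last event at or before ``t_grid[k]``
    (left-continuous piecewise-constant sampling).
    """
    ns = x0.size
    nr = rates.size
    L = t_grid.size
    n_slots = np.empty(nr, dtype=np.int64)
    for j in range(nr):
        c = 0
        for q in range(prop_idx.shape[1]):
            if prop_idx[j, q] >= 0:
                c += 1
        n_slots[j] = c
    out = np.empty((L, ns), dtype=np.int64)
    x = x0.copy()
    rng = _seed_state(seed)
    a = np.empty(nr, dtype=np.float64)
    eff_rates = np.empty(nr, dtype=np.float64)
    _set_light(rates, uses_light, s_init, eff_rates)
    a0 = _all_propensities(x, eff_rates, prop_idx, prop_off, n_slots, a)
    t = 0.0
    i_sw = 0
    n_sw = sw_t.size
    gi = 0
    events = 0
    refresh = 0
    while gi < L:
        next_sw = sw_t[i_sw] if i_sw < n_sw else np.inf
        if a0 <= 0.0:
            t_next = next_sw  # frozen until the light changes (or forever)
        else:
            u = _uniform(rng)
            while u <= 0.0:
                u = _uniform(rng)
            t_next = t + (-np.log(u) / a0)
        if t_next >= next_sw:
            while gi < L and t_grid[gi] < next_sw:
                for i in range(ns):
                    out[gi, i] = x[i]
                gi += 1
            if i_sw >= n_sw:  # frozen, no more switches: state is final
                while gi < L:
                    for i in range(ns):
                        out[gi, i] = x[i]
                    gi += 1
                break
            t = next_sw
            _set_light(rates, uses_light, sw_s[i_sw], eff_rates)
            i_sw += 1
            a0 = _all_propensities(x, eff_rates, prop_idx, prop_off, n_slots, a)
            continue
        while gi < L and t_grid[gi] < t_next:
            for i in range(ns):
                out[gi, i] = x[i]
            gi += 1
        if gi >= L:
            break
        t = t_next
        # select reaction
        target = _uniform(rng) * a0
        acc = 0.0
        r = nr - 1
        for j in range(nr):
            acc += a[j]
            if target < acc:
                r = j
                break
        # apply stoichiometry
        sp = st_sp[r, 0]
        if sp >= 0:
            x[sp] += st_dl[r, 0]
            sp = st_sp[r, 1]
            if sp >= 0:
                x[sp] += st_dl[r, 1]
        events += 1
        if events >= max_events:
            return out, events, MAX_EVENTS
        # incremental propensity update over dependents
        for k in range(dep.shape[1]):
            d = dep[r, k]
            if d < 0:
                break
            a0 -= a[d]
            a[d] = _propensity(d, x, eff_rates, prop_idx, prop_off, n_slots)
            a0 += a[d]
        refresh += 1
        if refresh >= 8192:  # control floating-point drift in the running sum
            a0 = _all_propensities(x, eff_rates, prop_idx, prop_off,
                                   n_slots, a)
            refresh = 0
    return out, events, OK


@njit(cache=True)
def ssa_events(rates, uses_light, prop_idx, prop_off, st_sp, st_dl, dep,
               x0, sw_t, sw_s, s_init, t_end, seed, max_events):
    """Direct-method trajectory with the full event history.

    Returns ``(times, states, n_events, status)``: ``times[0] = 0`` with the
    initial state; each subsequent row is the state after one reaction firing.
    Light-switch crossings are not events (the state does not change there).
    """
    ns = x0.size
    nr = rates.size
    n_slots = np.empty(nr, dtype=np.int64)
    for j in range(nr):
        c = 0
        for q in range(prop_idx.shape[1]):
            if prop_idx[j, q] >= 0:
                c += 1
        n_slots[j] = c
    cap = int(max_events) + 1
    times = np.empty(cap, dtype=np.float64)
    states = np.empty((cap, ns), dtype=np.int64)
    x = x0.copy()
    rng = _seed_state(seed)
    a = np.empty(nr, dtype=np.float64)
    eff_rates = np.empty(nr, dtype=np.float64)
    _set_light(rates, uses_light, s_init, eff_rates)
    a0 = _all_propensities(x, eff_rates, prop_idx, prop_off, n_slots, a)
    t = 0.0
    i_sw = 0
    n_sw = sw_t.size
    times[0] = 0.0
    for i in range(ns):
        states[0, i] = x[i]
    n = 1
    while True:
        next_sw = sw_t[i_sw] if i_sw < n_sw else np.inf
        if a0 <= 0.0:
            t_next = next_sw
            if not np.isfinite(t_next):
                break
        else:
            u = _uniform(rng)
            while u <= 0.0:
                u = _uniform(rng)
            t_next = t + (-np.log(u) / a0)
        if t_next >= t_end:
            break
        if t_next >= next_sw:
            t = next_sw
            _set_light(rates, uses_light, sw_s[i_sw], eff_rates)
            i_sw += 1
            a0 = _all_propensities(x, eff_rates, prop_idx, prop_off, n_slots, a)
            continue
        t = t_next
        target = _uniform(rng) * a0
        acc = 0.0
        r = nr - 1
        for j in range(nr):
            acc += a[j]
            if target < acc:
                r = j
                break
        for k in range(2):
            sp = st_sp[r, k]
            if sp >= 0:
                x[sp] += st_dl[r, k]
        if n >= cap:
            return times[:n], states[:n], n - 1, MAX_EVENTS
        times[n] = t
        for i in range(ns):
            states[n, i] = x[i]
        n += 1
        for k in range(dep.shape[1]):
            d = dep[r, k]
            if d < 0:
                break
            a0 -= a[d]
            a[d] = _propensity(d, x, eff_rates, prop_idx, prop_off, n_slots)
            a0 += a[d]
    return times[:n], states[:n], n - 1, OK
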