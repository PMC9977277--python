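"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the matching oracle
enumerates one-to-one assignments recursively, and the rheobase oracle
integrates the leaky integrate-and-fire ODE with an adaptive solver and an
event function.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def brute_force_match(pre_onsets, post_onsets, w_min=0.5, w_max=0.75,
                      step=0.01, directional=False):
    """Reference matching: exhaustive optimal assignment.

    Scans tolerance windows downward from w_max; the largest window at which
    the candidate graph has all degrees <= 1 fixes the matching.  If none
    exists, the window is w_max and the matching is the exhaustive
    max-cardinality, minimum-total-|lag| one-to-one assignment with ties
    broken toward earlier downstream bursts.  Returns {pre_idx: post_idx}.
    """
    pre = np.asarray(pre_onsets, dtype=float)
    post = np.asarray(post_onsets, dtype=float)
    if pre.size == 0 or post.size == 0:
        return {}
    lags = post[None, :] - pre[:, None]

    def feasible(w):
        if directional:
            return (lags >= -1e-12) & (lags <= w + 1e-12)
        return np.abs(lags) <= w + 1e-12

    n_steps = int(np.floor((w_max - w_min) / step + 1e-9))
    grid = [w_max - step * k for k in range(n_steps + 1)]
    if grid[-1] > w_min + 1e-12:
        grid.append(w_min)
    for w in grid:
        feas = feasible(w)
        if feas.sum(axis=1).max(initial=0) <= 1 \
                and feas.sum(axis=0).max(initial=0) <= 1:
            return {int(i): int(j) for i, j in np.argwhere(feas)}
    return _best_assignment(lags, feasible(w_max))


def _best_assignment(lags, feas):
    """Enumerate all one-to-one assignments over the feasibility graph.

    Ranking: max cardinality, then min total |lag|, then min total lag²
    (which uniquely selects the non-crossing pairing when total |lag| is
    permutation-invariant), then earliest downstream indices.
    """
    n_pre = lags.shape[0]
    best = {"key": None, "assign": {}}

    def recurse(i, used, assign, cost, cost_sq):
        if i == n_pre:
            key = (-len(assign), round(cost, 10), round(cost_sq, 10),
                   tuple(sorted(assign.values())))
            if best["key"] is None or key < best["key"]:
                best.update(key=key, assign=dict(assign))
            return
        recurse(i + 1, used, assign, cost, cost_sq)   # leave pre i unmatched
        for j in np.flatnonzero(feas[i]):
            if j not in used:
                assign[i] = int(j)
                recurse(i + 1, used | {int(j)}, assign,
                        cost + abs(lags[i, j]), cost_sq + lags[i, j] ** 2)
                del assign[i]

    recurse(0, frozenset(), {}, 0.0, 0.0)
    return best["assign"]


def lif_first_crossing(resistance_mohm, v_rest, v_threshold, tau_m,
                       ramp_rate, peak_current, step_duration=0.5,
                       prestep_pa=-100.0):
    """Numerically solve the LIF ODE for the first threshold crossing.

    Returns the commanded current (pA) at the crossing, or None if threshold
    is not reached before the ramp peak.  Independent route: adaptive RK45
    with a terminal event, versus the package's Euler simulation plus spike
    detection.
    """
    gain = resistance_mohm * 1e-3   # MΩ * pA -> mV

    def current(t):
        if t < step_duration:
            return prestep_pa
        return min(ramp_rate * (t - step_duration), peak_current)

    def rhs(t, y):
        return [(-(y[0] - v_rest) + gain * current(t)) / tau_m]

    def crossed(t, y):
        return y[0] - v_threshold
    crossed.terminal = True
    crossed.direction = 1

    t_end = step_duration + peak_current / ramp_rate
    sol = solve_ivp(rhs, (0.0, t_end), [v_rest], events=crossed,
                    max_step=1e-3, rtol=1e-8, atol=1e-8)
    if sol.t_events[0].size == 0:
        return None
    t_cross = float(sol.t_events[0][0])
    return min(ramp_rate * (t_cross - step_duration), peak_current)
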