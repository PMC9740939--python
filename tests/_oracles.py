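"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: regression uses
explicit normal-equation sums, areas use an explicit segment loop, and the
hypergeometric tail enumerates every draw.
"""

from __future__ import annotations

import itertools

import numpy as np


def ols_normal_equations(t, y):
    """Slope/intercept/adjusted-R2 from the explicit 2x2 normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    sx, sy = t.sum(), y.sum()
    sxx, sxy = (t * t).sum(), (t * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = y - (slope * t + intercept)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst <= 0 and sse <= 1e-300 else (0.0 if sst <= 0 else 1.0 - sse / sst)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, adj


def brute_force_lambda_z(times, concs, min_points=3):
    """Exhaustive-window terminal fit mirroring the published selection rule.

    Candidate pool: quantifiable points strictly after the (earliest) peak;
    if fewer than ``min_points``, the peak joins the pool.  Every trailing
    window of >= min_points points is refit from the normal equations; the
    window with the highest adjusted R2 (ties to the longer window) and a
    negative slope wins.  Returns (lambda_z, intercept, n_points, adj_r2) or
    None when no window qualifies.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    imax = int(np.argmax(concs))
    tail_t, tail_c = times[imax + 1:], concs[imax + 1:]
    if len(tail_t) < min_points:
        tail_t, tail_c = times[imax:], concs[imax:]
    pos = tail_c > 0
    tail_t, tail_c = tail_t[pos], tail_c[pos]
    if len(tail_t) < min_points:
        return None
    logc = np.log(tail_c)
    best = None
    for k in range(min_points, len(tail_t) + 1):
        slope, icpt, adj = ols_normal_equations(tail_t[-k:], logc[-k:])
        if slope >= 0:
            continue
        if best is None or adj > best[3] + 1e-12 or (
            abs(adj - best[3]) <= 1e-12 and k > best[2]
        ):
            best = (-slope, icpt, k, adj)
    return best


def trapezoid_sums(times, concs):
    """Segment-by-segment linear trapezoid AUC and AUMC."""
    auc = aumc = 0.0
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        auc += 0.5 * (concs[i] + concs[i + 1]) * dt
        aumc += 0.5 * (times[i] * concs[i] + times[i + 1] * concs[i + 1]) * dt
    return auc, aumc


def hypergeom_tail_enumerated(N: int, K: int, n: int, k: int) -> float:
    """P[overlap >= k] by enumerating every C(N, n) draw (feasible N <= ~14)."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_step_up(p):
    """Hand Benjamini-Hochberg step-up, scalar loop formulation."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, m * p[i] / rank)
        q[i] = val
        prev = val
    return q
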