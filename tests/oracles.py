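"""Independent reference implementations used as test oracles.

Everything here is deliberately written in the most literal style
possible (explicit loops over risk sets, finite differences instead of
analytic derivatives) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def reference_breslow_loglik(beta: float, x, time, event) -> float:
    """Breslow log partial likelihood, coded literally from its definition."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        events_here = np.flatnonzero((time == t) & (event == 1))
        risk_set = np.flatnonzero(time >= t)
        for i in events_here:
            ll += beta * x[i]
        ll -= len(events_here) * np.log(np.sum(np.exp(beta * x[risk_set])))
    return float(ll)


def numeric_cox_score(x, time, event, h: float = 1e-4) -> float:
    """Score statistic U(0)/sqrt(I(0)) via central finite differences of
    the reference log partial likelihood."""
    f = lambda b: reference_breslow_loglik(b, x, time, event)
    u = (f(h) - f(-h)) / (2 * h)
    info = -(f(h) - 2 * f(0.0) + f(-h)) / (h * h)
    return float(u / np.sqrt(info))


def pairwise_c_index(risk, time, event) -> float:
    """Harrell's C by exhaustive enumeration over all sample pairs."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = 0.0
    den = 0
    n = len(risk)
    for i in range(n):
        for j in range(i + 1, n):
            # order so a is the earlier time
            a, b = (i, j) if time[i] < time[j] else (j, i)
            if time[i] == time[j]:
                if event[i] != 1 and event[j] != 1:
                    continue
                # tied times: usable if at least one event; concordance is
                # ambiguous, count only the risk-tie credit
                den += 1
                if risk[i] == risk[j]:
                    num += 0.5
                elif event[i] == 1 and event[j] == 1:
                    num += 0.5
                else:
                    ev = i if event[i] == 1 else j
                    num += 1.0 if risk[ev] > risk[i + j - ev] else 0.0
                continue
            if event[a] != 1:
                continue  # shorter time censored: unusable
            den += 1
            if risk[a] > risk[b]:
                num += 1.0
            elif risk[a] == risk[b]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def hand_logrank_chi2(time_a, event_a, time_b, event_b) -> float:
    """Two-sample log-rank chi-square from the observed-minus-expected
    event counts, computed straight from the 2xK tables."""
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, int), np.asarray(event_b, int)
    times = sorted(set(np.r_[time_a[event_a == 1], time_b[event_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(time_a >= t)
        n2 = np.sum(time_b >= t)
        d1 = np.sum((time_a == t) & (event_a == 1))
        d2 = np.sum((time_b == t) & (event_b == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return float(o_minus_e**2 / var)
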