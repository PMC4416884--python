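"""Univariate Cox proportional-hazards internals (Breslow ties).

Everything here works on the Breslow partial likelihood

    ll(b) = sum_{events} b*x_i - sum_k d_k * log( sum_{j in R_k} exp(b*x_j) )

where k runs over distinct event times, d_k is the event count at t_k and
R_k = {j : t_j >= t_k} is the risk set (censored samples stay at risk
through their own time). The Newton fit standardizes x internally — the
likelihood-ratio statistic is invariant to affine rescaling — and caps
|beta| on the standardized scale to keep monotone-likelihood cases
(perfect separation) finite instead of diverging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "breslow_loglik", "fit_univariate_cox", "risk_set_layout"]

BETA_BOUND = 15.0  # on the SD-1 scale of x


@dataclass
class CoxFit:
    beta: float
    loglik: float
    loglik_null: float
    converged: bool
    at_bound: bool
    n_iter: int

    @property
    def likelihood_ratio(self) -> float:
        return max(0.0, 2.0 * (self.loglik - self.loglik_null))


def risk_set_layout(time: np.ndarray, event: np.ndarray):
    """Precompute the sorted layout shared by score and likelihood sums.

    Samples are sorted by descending time so each risk set R_k is a prefix
    of the sorted arrays. Returns ``(order, ends, d)`` where ``ends[k]`` is
    the inclusive end index of the k-th distinct *event* time's risk set
    and ``d[k]`` its event count; plus the sorted event mask for numerator
    sums.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="mergesort")
    ts = time[order]
    ev = event[order]
    # distinct-time group boundaries in the descending-sorted array
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    ends_all = np.r_[starts[1:], ts.size] - 1
    d_all = np.add.reduceat(ev, starts)
    has_event = d_all > 0
    return order, ev, starts[has_event], ends_all[has_event], d_all[has_event]


def breslow_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a univariate Cox model."""
    x = np.asarray(x, dtype=float)
    order, ev, starts, ends, d = risk_set_layout(time, event)
    xs = x[order]
    ex = np.exp(beta * xs)
    cum = np.cumsum(ex)
    num = float(beta * np.sum(xs[ev == 1]))
    return num - float(np.sum(d * np.log(cum[ends])))


def _derivatives(beta: float, xs, ev, starts, ends, d):
    """(ll, U, I) at beta for pre-sorted data."""
    ex = np.exp(beta * xs)
    s0 = np.cumsum(ex)[ends]
    s1 = np.cumsum(xs * ex)[ends]
    s2 = np.cumsum(xs * xs * ex)[ends]
    xbar = s1 / s0
    ll = beta * np.sum(xs[ev == 1]) - np.sum(d * np.log(s0))
    # per-event-time numerator sum of x over events
    ev_x = np.add.reduceat(xs * ev, starts)
    u = np.sum(ev_x - d * xbar)
    info = np.sum(d * (s2 / s0 - xbar * xbar))
    return float(ll), float(u), float(info)


def fit_univariate_cox(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    beta_bound: float = BETA_BOUND,
) -> CoxFit:
    """Newton fit of a one-covariate Cox model (Breslow ties).

    Raises ``ValueError`` for constant x or no events. A monotone partial
    likelihood is reported as ``at_bound=True`` with beta clamped at the
    bound; NaNs anywhere raise.
    """
    x = np.asarray(x, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events: Cox model undefined")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("constant covariate: zero information")
    z = (x - x.mean()) / sd

    order, ev, starts, ends, d = risk_set_layout(time, event)
    zs = z[order]

    beta = 0.0
    ll, u, info = _derivatives(beta, zs, ev, starts, ends, d)
    ll0 = ll
    converged = False
    at_bound = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            raise ValueError("non-positive information in Newton step")
        step = u / info
        step = float(np.clip(step, -2.0, 2.0))  # guard huge early steps
        new_beta = beta + step
        ll_new, u_new, info_new = _derivatives(new_beta, zs, ev, starts, ends, d)
        # step-halving if the likelihood did not improve
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            ll_new, u_new, info_new = _derivatives(new_beta, zs, ev, starts, ends, d)
            halvings += 1
        beta, ll, u, info = new_beta, ll_new, u_new, info_new
        if not np.isfinite(ll):
            raise ValueError(f"Cox fit diverged (non-finite log-likelihood at beta={beta:.3g})")
        if abs(beta) >= beta_bound:
            beta = float(np.clip(beta, -beta_bound, beta_bound))
            ll, u, info = _derivatives(beta, zs, ev, starts, ends, d)
            at_bound = True
            converged = True
            break
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise ValueError(
            f"Cox Newton fit did not converge in {max_iter} iterations "
            f"(beta={beta:.4g}, score={u:.3g}, info={info:.3g})"
        )
    return CoxFit(beta / sd, ll, ll0, converged, at_bound, it)
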