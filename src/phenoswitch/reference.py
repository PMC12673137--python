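"""Brute-force fixed-step reference integrator for cross-checks.

A deliberately simple, self-contained RK4 integrator for the one-drug
model, written independently of the production engine (its own
right-hand-side algebra, no compiled kernels, no segment/event
machinery beyond a linear replay).  It exists to validate the adaptive
solver: at a small step (default 1e-3 h) its error is far below the
agreement tolerance used in the validation suite.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .params import PSM1DParams
from .regimens import RegimenSchedule

__all__ = ["reference_states_psm1d"]


def _rhs(S, T, D, m_st, m_ts, m_b, pp):
    (beta0, n, Nmax, code, rational, a_st0, a_ts0,
     mu_st, lam_st, mu_ts, lam_ts, mu_b, lam_b, D50) = pp
    sat = D / (D + D50) if D > 0.0 else 0.0
    a_st = a_st0 * (1.0 + m_st) if pp.act else a_st0
    a_ts = a_ts0 / (1.0 + m_ts) if pp.inh_ts else a_ts0
    beta = beta0 / (1.0 + m_b) if pp.inh_b else beta0
    N = S + T
    if N > 0.0:
        if code == 0:
            P = beta
        elif code == 1:
            P = beta * (1.0 - N / Nmax)
        elif code == 2:
            P = beta * math.log(Nmax / max(N, 1e-3))
        else:
            r = (max(N, 0.0) / Nmax) ** n
            P = beta / (1.0 + r) if rational else beta * (1.0 - r)
        dS = P * S - a_st * S + a_ts * T
        dT = P * T + a_st * S - a_ts * T
    else:
        dS = dT = 0.0
    return (dS, dT,
            mu_st * sat - lam_st * m_st,
            mu_ts * sat - lam_ts * m_ts,
            mu_b * sat - lam_b * m_b)


class _PP(tuple):
    """Parameter tuple with the topology flags attached."""

    act = inh_ts = inh_b = False


def _pack(params: PSM1DParams) -> _PP:
    pr, sr, mem, d = params.prolif, params.switch, params.memory, params.drug
    pp = _PP((pr.beta, pr.n, pr.N_max, pr.code, int(pr.hill_rational),
              sr.alpha_ST0, sr.alpha_TS0,
              mem.ST.mu, mem.ST.lambda_, mem.TS.mu, mem.TS.lambda_,
              mem.beta.mu, mem.beta.lambda_, d.D_50))
    pp.act, pp.inh_ts, pp.inh_b = params.topology.flags
    return pp


def reference_states_psm1d(params: PSM1DParams, schedule: RegimenSchedule,
                           times: Sequence[float],
                           y0: Sequence[float] | None = None,
                           dt: float = 1e-3) -> np.ndarray:
    """States ``[S, T, D, M_ST, M_TS, M_beta]`` at the requested times.

    Fixed-step RK4 at step *dt* with the impulse applied at each event
    (kill ``S <- kappa S``; wash zeroes the drug before the dose is
    added).  At an event time the pre-impulse (left) state is reported.
    """
    times = np.asarray(times, dtype=float)
    order = np.argsort(times)
    tq = times[order]
    out = np.empty((times.size, 6))
    d = params.drug
    pp = _pack(params)

    if y0 is None:
        tot = params.switch.alpha_ST0 + params.switch.alpha_TS0
        s_frac = params.switch.alpha_TS0 / tot if tot > 0 else 1.0
        y0 = [10.0 * s_frac, 10.0 * (1 - s_frac), 0.0, 0.0, 0.0, 0.0]
    S, T, D, m_st, m_ts, m_b = (float(v) for v in y0)

    events = list(schedule.events)
    qi = 0  # pointer into the sorted query times

    def record_until(t_now, state_prev, t_prev, state_now):
        """Emit linear interpolants for queries in (t_prev, t_now]."""
        nonlocal qi
        while qi < tq.size and tq[qi] <= t_now + 1e-12:
            w = 0.0 if t_now == t_prev else (tq[qi] - t_prev) / (t_now - t_prev)
            out[order[qi]] = [(1 - w) * a + w * b
                              for a, b in zip(state_prev, state_now)]
            qi += 1

    t = 0.0
    if qi < tq.size and tq[qi] <= 1e-12:
        state = (S, T, D, m_st, m_ts, m_b)
        while qi < tq.size and tq[qi] <= 1e-12:
            out[order[qi]] = state
            qi += 1

    boundaries = sorted({0.0, schedule.horizon, *(e.time_h for e in events)})
    events_at = {e.time_h: e for e in events}
    for t_a, t_b in zip(boundaries[:-1], boundaries[1:]):
        ev = events_at.get(t_a)
        if ev is not None:
            if ev.wash:
                D = 0.0
            D += ev.dose
            if ev.dose > 0:
                S = d.kappa * S
        nsteps = max(1, int(math.ceil((t_b - t_a) / dt)))
        h = (t_b - t_a) / nsteps
        kd = d.k_d
        D_anchor, t_anchor = D, t_a
        t = t_a
        for _ in range(nsteps):
            prev = (S, T, D, m_st, m_ts, m_b)
            Da = max(0.0, D_anchor - kd * (t - t_anchor))
            Dm = max(0.0, D_anchor - kd * (t + 0.5 * h - t_anchor))
            Db = max(0.0, D_anchor - kd * (t + h - t_anchor))
            k1 = _rhs(S, T, Da, m_st, m_ts, m_b, pp)
            k2 = _rhs(S + 0.5 * h * k1[0], T + 0.5 * h * k1[1], Dm,
                      m_st + 0.5 * h * k1[2], m_ts + 0.5 * h * k1[3],
                      m_b + 0.5 * h * k1[4], pp)
            k3 = _rhs(S + 0.5 * h * k2[0], T + 0.5 * h * k2[1], Dm,
                      m_st + 0.5 * h * k2[2], m_ts + 0.5 * h * k2[3],
                      m_b + 0.5 * h * k2[4], pp)
            k4 = _rhs(S + h * k3[0], T + h * k3[1], Db,
                      m_st + h * k3[2], m_ts + h * k3[3],
                      m_b + h * k3[4], pp)
            S += (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            T += (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            m_st += (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            m_ts += (h / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            m_b += (h / 6.0) * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            t += h
            D = Db
            record_until(t, prev, t - h, (S, T, D, m_st, m_ts, m_b))
        # queries sitting exactly on the boundary get the left limit even
        # when accumulated rounding leaves t marginally below t_b
        state = (S, T, D, m_st, m_ts, m_b)
        while qi < tq.size and tq[qi] <= t_b + 1e-9:
            out[order[qi]] = state
            qi += 1
    return out
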