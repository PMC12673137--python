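"""One-drug phenotypic switch model (PSM1D): dynamics and simulation.

The model tracks a sensitive compartment S and a tolerant compartment T
(both in % of dish area), the dish drug concentration D, and three
memory variables that carry the retained drug effect acting on the
switching rates and on proliferation.  Between drug inputs the system
follows smooth ODEs; at each input the drug concentration is reset and
the sensitive compartment is (by default completely) removed as an
impulse.

State vector ordering used throughout: ``[S, T, D, M_ST, M_TS, M_beta]``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _fast
from .params import (DrugId, DrugParams, MemoryParams, PSM1DParams,
                     ProliferationParams, SwitchRates, Topology)
from .regimens import RegimenSchedule
from .trajectory import Trajectory

__all__ = [
    "SimulationError",
    "proliferation_rate",
    "drug_concentration",
    "memory_derivative",
    "effective_rates",
    "psm1d_rhs",
    "apply_impulse",
    "initial_state_psm1d",
    "simulate_psm1d",
]

STATE_COLUMNS = ("S", "T", "D", "M_ST", "M_TS", "M_beta")


class SimulationError(RuntimeError):
    """Raised when integration fails or a state invariant is violated."""


# ---------------------------------------------------------------------------
# elementary operations


def proliferation_rate(p: ProliferationParams, N: float) -> float:
    """Per-capita proliferation rate P(theta, N) in 1/h.

    The default Hill law ``beta * (1 - (N/N_max)**n)`` vanishes at the
    carrying capacity; exponential / logistic / Gompertz candidates are
    selected through ``p.model_id``.  The Gompertz rate is capped near
    N = 0 to avoid its logarithmic singularity.
    """
    if N < 0 or N > p.N_max:
        raise ValueError(f"N must lie in [0, N_max={p.N_max}], got {N}")
    return float(_fast.prolif_rate(p.code, int(p.hill_rational), p.beta, p.n,
                                   p.N_max, float(N)))


def _drug_levels_over_events(schedule: RegimenSchedule,
                             decay: dict[DrugId, float]):
    """Replay the event list; yield (event, levels_before, levels_after).

    ``levels`` maps every drug id present in *decay* to its dish
    concentration.  A wash zeroes all drugs before the event's own dose
    is applied; a dose without wash is additive.
    """
    levels = {d: 0.0 for d in decay}
    t_prev = 0.0
    for ev in schedule.events:
        before = {
            d: max(0.0, lv - decay[d] * (ev.time_h - t_prev))
            for d, lv in levels.items()
        }
        after = dict(before)
        if ev.wash:
            after = {d: 0.0 for d in after}
        if ev.drug_id in after:
            after[ev.drug_id] += ev.dose
        yield ev, before, after
        levels = after
        t_prev = ev.time_h


def drug_concentration(schedule: RegimenSchedule, d: DrugParams, t: float,
                       side: str = "right") -> float:
    """Dish concentration of drug *d* at time *t* under *schedule*.

    Piecewise-linear decay at slope ``-k_d`` floored at zero; reset (not
    added) to the administered dose at each wash + treat event.  At an
    event time the right limit (post-input) is returned unless
    ``side='left'``.
    """
    if t < 0 or t > schedule.horizon:
        raise ValueError(f"t={t} outside [0, horizon={schedule.horizon}]")
    level, t_anchor = 0.0, 0.0
    for ev, before, after in _drug_levels_over_events(schedule, {d.drug_id: d.k_d}):
        if ev.time_h > t or (ev.time_h == t and side == "left"):
            break
        level, t_anchor = after[d.drug_id], ev.time_h
    return max(0.0, level - d.k_d * (t - t_anchor))


def memory_derivative(M: float, D: float, mp: MemoryParams,
                      d: DrugParams) -> float:
    """dM/dt = mu * D / (D + D_50) - lambda * M.

    The Emax-type saturation keeps the drug-stress input bounded; at
    constant D the memory relaxes to ``(mu/lambda) * D / (D + D_50)``.
    """
    if M < -1e-9 or D < -1e-9:
        raise ValueError("M and D must be >= 0")
    M, D = max(M, 0.0), max(D, 0.0)
    return mp.mu * D / (D + d.D_50) - mp.lambda_ * M


def effective_rates(topo: Topology, sr: SwitchRates, p: ProliferationParams,
                    M_ST: float, M_TS: float, M_beta: float
                    ) -> tuple[float, float, float]:
    """Memory-modulated switching and proliferation rates.

    Activation multiplies a rate by ``(1 + M)``; inhibition divides by
    ``(1 + M)``.  Both are identity at M = 0 and keep rates positive.
    """
    if min(M_ST, M_TS, M_beta) < -1e-9:   # solver-level noise is tolerated
        raise ValueError("memory levels must be >= 0")
    M_ST, M_TS, M_beta = (max(m, 0.0) for m in (M_ST, M_TS, M_beta))
    a_st = sr.alpha_ST0 * (1.0 + M_ST) if topo.activate_ST else sr.alpha_ST0
    a_ts = sr.alpha_TS0 / (1.0 + M_TS) if topo.inhibit_TS else sr.alpha_TS0
    beta = p.beta / (1.0 + M_beta) if topo.inhibit_beta else p.beta
    return a_st, a_ts, beta


def psm1d_rhs(x: Sequence[float], t: float, params: PSM1DParams) -> np.ndarray:
    """Continuous part of the PSM1D dynamics on ``[S,T,D,M_ST,M_TS,M_beta]``.

    Because daughter cells inherit their mother's phenotype, each
    compartment's renewal share of the global proliferation reduces to
    ``P(N) * S`` and ``P(N) * T``; switching moves density between the two
    without changing the total.  An empty dish (N = 0) is absorbing.
    """
    S, T, D, m_st, m_ts, m_b = (float(v) for v in x)
    a_st, a_ts, beta = effective_rates(params.topology, params.switch,
                                      params.prolif, m_st, m_ts, m_b)
    N = S + T
    if N > 0:
        P = _fast.prolif_rate(params.prolif.code, int(params.prolif.hill_rational),
                              beta, params.prolif.n, params.prolif.N_max, N)
        dS = P * S - a_st * S + a_ts * T
        dT = P * T + a_st * S - a_ts * T
    else:
        dS = dT = 0.0
    dD = -params.drug.k_d if D > 0 else 0.0
    return np.array([
        dS, dT, dD,
        memory_derivative(m_st, D, params.memory.ST, params.drug),
        memory_derivative(m_ts, D, params.memory.TS, params.drug),
        memory_derivative(m_b, D, params.memory.beta, params.drug),
    ])


def apply_impulse(x: Sequence[float], d: DrugParams, dose: float | None = None,
                  wash: bool = True) -> np.ndarray:
    """Impulsive drug input: kill sensitive cells, reset the drug level.

    ``S <- kappa * S`` (kappa = 0 by default: the sensitive compartment
    is removed entirely); ``D`` is reset to the dose when the dish is
    washed, added otherwise.  T and the memory variables are continuous.
    """
    x = np.array(x, dtype=float)
    if dose is None:
        dose = d.D_input
    if dose > 0:
        x[0] = d.kappa * x[0]
    x[2] = dose if wash else x[2] + dose
    return x


# ---------------------------------------------------------------------------
# simulation engine


def initial_state_psm1d(params: PSM1DParams, N0: float = 10.0) -> np.ndarray:
    """Drug-naive initial state: N0 split at the switching equilibrium."""
    sr = params.switch
    tot = sr.alpha_ST0 + sr.alpha_TS0
    s_frac = sr.alpha_TS0 / tot if tot > 0 else 1.0
    return np.array([N0 * s_frac, N0 * (1 - s_frac), 0.0, 0.0, 0.0, 0.0])


def _param_vector(params: PSM1DParams) -> np.ndarray:
    pr, sr, mem = params.prolif, params.switch, params.memory
    return np.array([
        pr.beta, pr.n, pr.N_max, pr.code, int(pr.hill_rational),
        sr.alpha_ST0, sr.alpha_TS0,
        mem.ST.mu, mem.ST.lambda_, mem.TS.mu, mem.TS.lambda_,
        mem.beta.mu, mem.beta.lambda_,
    ])


def _split_at_drug_zero(t_a: float, t_b: float, D0: float, kd: float):
    """Sub-segments with smooth D: split where the decay hits the floor."""
    if D0 > 0 and kd > 0:
        tc = t_a + D0 / kd
        if tc < t_b - 1e-12:
            return [(t_a, tc, D0), (tc, t_b, 0.0)]
    return [(t_a, t_b, D0)]


def _integrate_1d_adaptive(y, t_a, t_b, D0, kd, D50, pvec, flags, pts,
                           rtol, atol, method):
    out = np.empty(5)

    def fun(t, yv):
        D = max(0.0, D0 - kd * (t - t_a))
        _fast._rhs1d(yv, D, D50, pvec, *flags, out)
        return out.copy()

    t_eval = np.unique(np.append(pts, t_b))
    sol = solve_ivp(fun, (t_a, t_b), y, t_eval=t_eval, rtol=rtol, atol=atol,
                    method=method)
    if not sol.success:
        raise SimulationError(f"solver failed on [{t_a}, {t_b}]: {sol.message}")
    vals = sol.y.T
    keep = np.isin(sol.t, pts)
    return vals[keep], vals[-1]


def _integrate_1d_fixed(y, t_a, t_b, D0, kd, D50, pvec, flags, pts, dt):
    ts, ys = _fast.integrate_segment_1d(y, t_a, t_b, dt, D0, kd, D50, pvec,
                                        *flags)
    sampled = np.column_stack([np.interp(pts, ts, ys[:, j]) for j in range(5)])
    return sampled, ys[-1]


def simulate_psm1d(params: PSM1DParams, schedule: RegimenSchedule,
                   y0: Sequence[float] | None = None, *,
                   method: str = "adaptive", solver: str = "RK45",
                   dt: float = 0.05, rtol: float = 1e-10, atol: float = 1e-12,
                   dense_interval: float = 0.5,
                   t_eval: Sequence[float] | None = None,
                   check_invariants: bool = True) -> Trajectory:
    """Simulate the impulsive PSM1D over a treatment schedule.

    Integration proceeds on half-open intervals between drug inputs; at
    each input the impulse (kill + drug reset) is applied and integration
    restarts from the right limit.  The trajectory stores both limits at
    every impulse time; the returned grid is the union of the schedule's
    observation times and a dense grid at ``dense_interval`` (or exactly
    ``t_eval`` when given).

    ``method='adaptive'`` uses an adaptive solver at (``rtol``, ``atol``);
    ``method='fixed'`` uses the fixed-step RK4 kernel with step ``dt``.
    """
    if y0 is None:
        y0 = initial_state_psm1d(params)
    y0 = np.asarray(y0, dtype=float)
    if y0.size == 2:
        y0 = np.array([y0[0], y0[1], 0.0, 0.0, 0.0, 0.0])
    if y0.size != 6:
        raise ValueError("y0 must have 2 (S, T) or 6 components")
    if np.any(y0 < 0):
        raise ValueError("initial state components must be >= 0")

    horizon = schedule.horizon
    if t_eval is None:
        t_out = np.unique(np.concatenate([
            schedule.observation_times(),
            np.arange(0.0, horizon + 1e-9, dense_interval),
            [horizon],
        ]))
    else:
        t_out = np.unique(np.asarray(t_eval, dtype=float))
        if t_out.size and (t_out[0] < 0 or t_out[-1] > horizon):
            raise ValueError("t_eval must lie within [0, horizon]")

    d = params.drug
    pvec = _param_vector(params)
    flags = tuple(int(f) for f in params.topology.flags)

    y = y0[[0, 1, 3, 4, 5]].copy()   # S, T, M_ST, M_TS, M_beta
    D_level = float(y0[2])

    rows_t: list[float] = []
    rows: list[np.ndarray] = []
    imp_t: list[float] = []
    imp_L: list[np.ndarray] = []
    imp_R: list[np.ndarray] = []

    def full_state(yv, D):
        return np.array([yv[0], yv[1], D, yv[2], yv[3], yv[4]])

    boundaries = sorted({0.0, horizon, *(e.time_h for e in schedule.events)})
    events_at = {e.time_h: e for e in schedule.events}

    if t_out.size and t_out[0] == 0.0:
        rows_t.append(0.0)
        rows.append(full_state(y, D_level))

    for t_a, t_b in zip(boundaries[:-1], boundaries[1:]):
        ev = events_at.get(t_a)
        if ev is not None:
            left = full_state(y, D_level)
            if ev.wash:
                D_level = 0.0
            D_level += ev.dose
            if ev.dose > 0:
                y[0] = d.kappa * y[0]
            right = full_state(y, D_level)
            imp_t.append(t_a)
            imp_L.append(left)
            imp_R.append(right)
            rows_t.append(t_a)
            rows.append(right)
        for s_a, s_b, D0 in _split_at_drug_zero(t_a, t_b, D_level, d.k_d):
            pts = t_out[(t_out > s_a + 1e-12) & (t_out <= s_b + 1e-12)]
            pts = np.clip(pts, s_a, s_b)
            try:
                if method == "adaptive":
                    sampled, y = _integrate_1d_adaptive(
                        y, s_a, s_b, D0, d.k_d, d.D_50, pvec, flags, pts,
                        rtol, atol, solver)
                elif method == "fixed":
                    sampled, y = _integrate_1d_fixed(
                        y, s_a, s_b, D0, d.k_d, d.D_50, pvec, flags, pts, dt)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except SimulationError:
                raise
            except Exception as exc:   # pragma: no cover - diagnostic wrapper
                raise SimulationError(
                    f"integration failed on [{s_a}, {s_b}] "
                    f"(topology {params.topology.label()}): {exc}") from exc
            for tq, yv in zip(pts, sampled):
                Dq = max(0.0, D0 - d.k_d * (tq - s_a))
                rows_t.append(float(tq))
                rows.append(full_state(yv, Dq))
            D_level = max(0.0, D0 - d.k_d * (s_b - s_a))

    # event exactly at the horizon (left limit already stored by the loop end)
    ev = events_at.get(horizon)
    if ev is not None:
        left = full_state(y, D_level)
        if ev.wash:
            D_level = 0.0
        D_level += ev.dose
        if ev.dose > 0:
            y[0] = d.kappa * y[0]
        right = full_state(y, D_level)
        imp_t.append(horizon)
        imp_L.append(left)
        imp_R.append(right)
        rows_t.append(horizon)
        rows.append(right)

    order = np.argsort(rows_t, kind="stable")
    times = np.asarray(rows_t, dtype=float)[order]
    states = np.asarray(rows)[order]

    k = len(STATE_COLUMNS)
    traj = Trajectory(times=times, states=states, columns=STATE_COLUMNS,
                      impulse_times=np.asarray(imp_t),
                      impulse_left=np.asarray(imp_L).reshape(len(imp_t), k),
                      impulse_right=np.asarray(imp_R).reshape(len(imp_t), k))
    if check_invariants:
        _check_invariants_1d(traj, params)
    return traj


def _check_invariants_1d(traj: Trajectory, params: PSM1DParams) -> None:
    if traj.states.size and traj.states.min() < -1e-9:
        raise SimulationError(
            f"negative state component ({traj.states.min():.3e}) exceeds tolerance")
    if params.prolif.model_id.value != "exponential" and not params.prolif.hill_rational:
        excess = traj.N.max() - params.prolif.N_max
        if excess > 1e-6:
            raise SimulationError(
                f"total density exceeds carrying capacity by {excess:.3e}")
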