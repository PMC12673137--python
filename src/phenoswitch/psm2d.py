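"""Two-drug phenotypic switch model (PSM2D).

Couples the apoptosis (drug A) and necroptosis (drug N) one-drug models
into a three-compartment system: S_A (sensitive to the pro-apoptotic
drug), S_N (sensitive to the pro-necroptotic drug) and T (tolerant to
both).  All switching traffic routes through T.  The pro-apoptotic drug
sensitizes tolerant cells to necroptosis by charging a dedicated memory
variable that activates the T -> S_N rate.

State vector ordering: ``[S_A, S_N, T, D_A, D_N, M_A_ST, M_A_TS,
M_A_beta, M_N_ST, M_N_TS, M_N_beta, M_TSN]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fast
from .model import SimulationError, simulate_psm1d
from .params import DrugId, PSM1DParams, PSM2DParams
from .regimens import RegimenSchedule
from .trajectory import Trajectory

__all__ = [
    "STATE_COLUMNS_2D",
    "DEFAULT_KILL_SETS",
    "psm2d_rhs",
    "initial_state_psm2d",
    "simulate_psm2d",
    "CrossingReport",
    "detect_threshold_crossing",
    "compare_regimens",
]

STATE_COLUMNS_2D = ("S_A", "S_N", "T", "D_A", "D_N",
                    "M_A_ST", "M_A_TS", "M_A_beta",
                    "M_N_ST", "M_N_TS", "M_N_beta", "M_TSN")

#: which sensitive compartments each drug's impulse removes.  The
#: necroptotic combination contains the apoptotic ligand, so its default
#: kill set covers both sensitive compartments.
DEFAULT_KILL_SETS: dict[DrugId, tuple[str, ...]] = {
    DrugId.A: ("S_A",),
    DrugId.N: ("S_A", "S_N"),
}

_KILL_IDX = {"S_A": 0, "S_N": 1}


def _param_vector_2d(params: PSM2DParams) -> np.ndarray:
    a, n, c = params.drug_A, params.drug_N, params.coupling
    pr = a.prolif
    return np.array([
        pr.beta, pr.n, pr.N_max, pr.code, int(pr.hill_rational),
        a.switch.alpha_ST0, a.switch.alpha_TS0,
        a.memory.ST.mu, a.memory.ST.lambda_, a.memory.TS.mu,
        a.memory.TS.lambda_, a.memory.beta.mu, a.memory.beta.lambda_,
        a.drug.D_50,
        n.switch.alpha_ST0, n.switch.alpha_TS0,
        n.memory.ST.mu, n.memory.ST.lambda_, n.memory.TS.mu,
        n.memory.TS.lambda_, n.memory.beta.mu, n.memory.beta.lambda_,
        n.drug.D_50,
        c.mu_TSN, c.lambda_TSN,
    ])


def _topo_flags_2d(params: PSM2DParams) -> tuple[int, ...]:
    return tuple(int(f) for f in (*params.drug_A.topology.flags,
                                  *params.drug_N.topology.flags))


def psm2d_rhs(x: Sequence[float], t: float, params: PSM2DParams) -> np.ndarray:
    """Continuous dynamics on the full 12-component state vector.

    The shared per-capita proliferation P acts on all three compartments
    at the total density N = S_A + S_N + T, so switching conserves N.
    """
    x = np.asarray(x, dtype=float)
    y = x[[0, 1, 2, 5, 6, 7, 8, 9, 10, 11]].copy()
    out = np.empty(10)
    _fast._rhs2d(y, max(x[3], 0.0), max(x[4], 0.0), _param_vector_2d(params),
                 *_topo_flags_2d(params), out)
    dDA = -params.drug_A.drug.k_d if x[3] > 0 else 0.0
    dDN = -params.drug_N.drug.k_d if x[4] > 0 else 0.0
    full = np.empty(12)
    full[[0, 1, 2]] = out[[0, 1, 2]]
    full[3], full[4] = dDA, dDN
    full[[5, 6, 7, 8, 9, 10, 11]] = out[[3, 4, 5, 6, 7, 8, 9]]
    return full


def initial_state_psm2d(params: PSM2DParams, N0: float = 10.0) -> np.ndarray:
    """Drug-naive state: N0 split at the three-compartment switching
    equilibrium (the stationary distribution of the zero-memory switching
    generator, which proliferation leaves untouched)."""
    a_sat = params.drug_A.switch.alpha_ST0
    a_tsa = params.drug_A.switch.alpha_TS0
    a_snt = params.drug_N.switch.alpha_ST0
    a_tsn = params.drug_N.switch.alpha_TS0
    Q = np.array([
        [-a_sat, 0.0, a_tsa],
        [0.0, -a_snt, a_tsn],
        [a_sat, a_snt, -(a_tsa + a_tsn)],
    ])
    _, _, vh = np.linalg.svd(Q)
    v = np.abs(vh[-1])
    v = v / v.sum()
    y = np.zeros(12)
    y[[0, 1, 2]] = N0 * v
    return y


def simulate_psm2d(params: PSM2DParams, schedule: RegimenSchedule,
                   y0: Sequence[float] | None = None, *,
                   kill_sets: Mapping[DrugId, tuple[str, ...]] | None = None,
                   method: str = "adaptive", solver: str = "RK45",
                   dt: float = 0.05, rtol: float = 1e-10, atol: float = 1e-12,
                   dense_interval: float = 0.5,
                   t_eval: Sequence[float] | None = None,
                   check_invariants: bool = True) -> Trajectory:
    """Simulate the coupled two-drug model over a schedule.

    Each drug's concentration and memory variables evolve independently;
    a wash removes both drugs from the dish.  A drug input removes the
    sensitive compartments in its kill set (scaled by that drug's
    surviving fraction kappa).
    """
    if kill_sets is None:
        kill_sets = DEFAULT_KILL_SETS
    if y0 is None:
        y0 = initial_state_psm2d(params)
    y0 = np.asarray(y0, dtype=float)
    if y0.size == 3:
        full = np.zeros(12)
        full[[0, 1, 2]] = y0
        y0 = full
    if y0.size != 12:
        raise ValueError("y0 must have 3 (S_A, S_N, T) or 12 components")
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

    drugs = {DrugId.A: params.drug_A.drug, DrugId.N: params.drug_N.drug}
    pvec = _param_vector_2d(params)
    flags = _topo_flags_2d(params)

    y = y0[[0, 1, 2, 5, 6, 7, 8, 9, 10, 11]].copy()
    levels = {DrugId.A: float(y0[3]), DrugId.N: float(y0[4])}

    rows_t: list[float] = []
    rows: list[np.ndarray] = []
    imp_t: list[float] = []
    imp_L: list[np.ndarray] = []
    imp_R: list[np.ndarray] = []

    def full_state(yv, lv):
        return np.array([yv[0], yv[1], yv[2], lv[DrugId.A], lv[DrugId.N],
                         *yv[3:]])

    def apply_event(ev):
        left = full_state(y, levels)
        if ev.wash:
            for k in levels:
                levels[k] = 0.0
        levels[ev.drug_id] += ev.dose
        if ev.dose > 0:
            kappa = drugs[ev.drug_id].kappa
            for comp in kill_sets.get(ev.drug_id, ()):
                y[_KILL_IDX[comp]] *= kappa
        right = full_state(y, levels)
        imp_t.append(ev.time_h)
        imp_L.append(left)
        imp_R.append(right)
        rows_t.append(ev.time_h)
        rows.append(right)

    boundaries = sorted({0.0, horizon, *(e.time_h for e in schedule.events)})
    events_at = {e.time_h: e for e in schedule.events}

    if t_out.size and t_out[0] == 0.0:
        rows_t.append(0.0)
        rows.append(full_state(y, levels))

    out = np.empty(10)
    for t_a, t_b in zip(boundaries[:-1], boundaries[1:]):
        ev = events_at.get(t_a)
        if ev is not None:
            apply_event(ev)
        # split where either drug's linear decay reaches zero
        cuts = {t_a, t_b}
        for did, d in drugs.items():
            if levels[did] > 0 and d.k_d > 0:
                tc = t_a + levels[did] / d.k_d
                if t_a + 1e-12 < tc < t_b - 1e-12:
                    cuts.add(tc)
        DA0, DN0 = levels[DrugId.A], levels[DrugId.N]
        kdA, kdN = drugs[DrugId.A].k_d, drugs[DrugId.N].k_d
        for s_a, s_b in zip(sorted(cuts)[:-1], sorted(cuts)[1:]):
            DA_s = max(0.0, DA0 - kdA * (s_a - t_a))
            DN_s = max(0.0, DN0 - kdN * (s_a - t_a))
            kdA_s = kdA if DA_s > 0 else 0.0
            kdN_s = kdN if DN_s > 0 else 0.0
            pts = t_out[(t_out > s_a + 1e-12) & (t_out <= s_b + 1e-12)]
            pts = np.clip(pts, s_a, s_b)
            try:
                if method == "adaptive":
                    def fun(t, yv, _sa=s_a, _DA=DA_s, _DN=DN_s,
                            _kA=kdA_s, _kN=kdN_s):
                        DA = max(0.0, _DA - _kA * (t - _sa))
                        DN = max(0.0, _DN - _kN * (t - _sa))
                        _fast._rhs2d(yv, DA, DN, pvec, *flags, out)
                        return out.copy()

                    sol = solve_ivp(fun, (s_a, s_b), y,
                                    t_eval=np.unique(np.append(pts, s_b)),
                                    rtol=rtol, atol=atol, method=solver)
                    if not sol.success:
                        raise SimulationError(
                            f"solver failed on [{s_a}, {s_b}]: {sol.message}")
                    vals = sol.y.T
                    sampled = vals[np.isin(sol.t, pts)]
                    y = vals[-1].copy()
                elif method == "fixed":
                    ts, ys = _fast.integrate_segment_2d(
                        y, s_a, s_b, dt, DA_s, kdA_s, DN_s, kdN_s, pvec, *flags)
                    sampled = np.column_stack(
                        [np.interp(pts, ts, ys[:, j]) for j in range(10)])
                    y = ys[-1].copy()
                else:
                    raise ValueError(f"unknown method {method!r}")
            except SimulationError:
                raise
            except Exception as exc:   # pragma: no cover
                raise SimulationError(
                    f"integration failed on [{s_a}, {s_b}]: {exc}") from exc
            for tq, yv in zip(pts, sampled):
                lv = {DrugId.A: max(0.0, DA_s - kdA_s * (tq - s_a)),
                      DrugId.N: max(0.0, DN_s - kdN_s * (tq - s_a))}
                rows_t.append(float(tq))
                rows.append(full_state(yv, lv))
        levels[DrugId.A] = max(0.0, DA0 - kdA * (t_b - t_a))
        levels[DrugId.N] = max(0.0, DN0 - kdN * (t_b - t_a))

    ev = events_at.get(horizon)
    if ev is not None:
        apply_event(ev)

    order = np.argsort(rows_t, kind="stable")
    times = np.asarray(rows_t, dtype=float)[order]
    states = np.asarray(rows)[order]
    k = len(STATE_COLUMNS_2D)
    traj = Trajectory(times=times, states=states, columns=STATE_COLUMNS_2D,
                      impulse_times=np.asarray(imp_t),
                      impulse_left=np.asarray(imp_L).reshape(len(imp_t), k),
                      impulse_right=np.asarray(imp_R).reshape(len(imp_t), k))
    if check_invariants:
        if traj.states.size and traj.states.min() < -1e-9:
            raise SimulationError(
                f"negative state component ({traj.states.min():.3e})")
        pr = params.drug_A.prolif
        if pr.model_id.value != "exponential" and not pr.hill_rational:
            excess = traj.N.max() - pr.N_max
            if excess > 1e-6:
                raise SimulationError(
                    f"total density exceeds carrying capacity by {excess:.3e}")
    return traj


# ---------------------------------------------------------------------------
# post-simulation event detection and regimen comparison


@dataclass(frozen=True)
class CrossingReport:
    """First crossing times (hours) of the extinction / occupation thresholds."""

    extinction_time: float | None
    occupation_time: float | None
    extinction_threshold: float
    occupation_threshold: float


def detect_threshold_crossing(traj: Trajectory,
                              extinction_threshold: float = 0.1,
                              occupation_threshold: float = 99.5,
                              N_max: float = 100.0) -> CrossingReport:
    """First times at which total density leaves the viable band.

    Returns the first time N(t) drops below the extinction threshold and
    the first time it exceeds the occupation threshold (linear
    interpolation between samples; a jump at an impulse crosses exactly
    at the impulse time).  ``None`` where never crossed.
    """
    for thr in (extinction_threshold, occupation_threshold):
        if not 0.0 < thr < N_max:
            raise ValueError(f"threshold {thr} outside (0, {N_max})")
    N = traj.N
    t = traj.times

    def first_below(thr):
        if N[0] < thr:
            return float(t[0])
        for i in range(1, N.size):
            if N[i] < thr <= N[i - 1]:
                if t[i] == t[i - 1]:
                    return float(t[i])
                w = (N[i - 1] - thr) / (N[i - 1] - N[i])
                return float(t[i - 1] + w * (t[i] - t[i - 1]))
        return None

    def first_above(thr):
        if N[0] > thr:
            return float(t[0])
        for i in range(1, N.size):
            if N[i] > thr >= N[i - 1]:
                if t[i] == t[i - 1]:
                    return float(t[i])
                w = (thr - N[i - 1]) / (N[i] - N[i - 1])
                return float(t[i - 1] + w * (t[i] - t[i - 1]))
        return None

    return CrossingReport(first_below(extinction_threshold),
                          first_above(occupation_threshold),
                          extinction_threshold, occupation_threshold)


def compare_regimens(params: PSM1DParams | PSM2DParams,
                     regimens: Mapping[str, RegimenSchedule],
                     horizon: float | None = None, *,
                     extinction_threshold: float = 0.1,
                     occupation_threshold: float = 99.5,
                     **sim_kwargs) -> tuple[pd.DataFrame, dict[str, CrossingReport]]:
    """Simulate every regimen and tabulate densities at observation times.

    Returns one row per regimen x observation time (total density,
    compartment densities, persister fraction T/N in %) plus a
    per-regimen threshold-crossing report.  Deterministic given inputs.
    """
    if not regimens:
        raise ValueError("regimen set must not be empty")
    two_drug = isinstance(params, PSM2DParams)
    records = []
    crossings: dict[str, CrossingReport] = {}
    for name, sched in regimens.items():
        if horizon is not None:
            sched = sched.with_horizon(horizon)
        traj = (simulate_psm2d if two_drug else simulate_psm1d)(
            params, sched, **sim_kwargs)
        obs = sched.observation_times()
        vals = traj.sample(obs, side="left")
        cols = traj.columns
        Nv = traj.sample_N(obs, side="left")
        T = vals[:, cols.index("T")]
        for i, tq in enumerate(obs):
            rec = {"regimen": name, "time_h": float(tq), "N": float(Nv[i]),
                   "persister_fraction_pct":
                       float(100.0 * T[i] / Nv[i]) if Nv[i] > 0 else np.nan}
            for c in traj.density_columns:
                rec[c] = float(vals[i, cols.index(c)])
            records.append(rec)
        crossings[name] = detect_threshold_crossing(
            traj, extinction_threshold, occupation_threshold)
    return pd.DataFrame.from_records(records), crossings
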