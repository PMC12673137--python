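"""Model calibration: growth-law selection, penalized least-squares
fitting of the one-drug model per topology, RMSE topology grids and
estimation of the two-drug coupling.

All fits minimize a weighted sum of squared differences between the
model and the observed densities on the dataset's own (24-h) time grid,
plus a quadratic exterior penalty on parameter-bound violations.
Compartment-resolved observations (S and T rows) are matched to the
corresponding model compartments; total-density rows are matched to
N = S + T.  Goodness of fit is always reported as the RMSE of the total
density at the observation times.

Free parameters are positive rates spanning several decades, so the
search runs in log space.  The default optimizer is a multi-start
trust-region least-squares solver on the residual vector (the start
beyond the supplied initial guess are drawn log-uniformly between the
bounds from a seeded generator); a bounded derivative-free Powell search
on the scalar cost is available as a fallback.  Every calibration is
reproducible bit-for-bit given its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import _fast
from .params import (CouplingParams, DrugId, DrugParams, MemoryBank,
                     MemoryParams, PSM1DParams, PSM2DParams,
                     ProliferationParams, SwitchRates, Topology,
                     all_topologies)
from .psm2d import DEFAULT_KILL_SETS, _param_vector_2d, _topo_flags_2d
from .regimens import RegimenSchedule, three_regimens
from .synthetic import ObservationSet

__all__ = [
    "aic", "rmse", "ModelComparisonRecord", "ProliferationFit",
    "fit_proliferation", "growth_curve", "free_parameter_spec",
    "PSM1DCostFunction", "CalibrationResult", "calibrate_psm1d",
    "TopologyGridResult", "topology_grid", "calibrate_coupling",
]

_SENTINEL_COST = 1e12
_SENTINEL_RESID = 1e4


# ---------------------------------------------------------------------------
# information criteria and error metrics


def aic(RSS: float, k: int, m: int) -> float:
    """Least-squares Akaike information criterion, m ln(RSS/m) + 2k."""
    if m <= 0:
        raise ValueError("m must be > 0")
    if RSS < 0:
        raise ValueError("RSS must be >= 0")
    if RSS == 0:
        warnings.warn("RSS = 0: AIC is -inf (perfect fit)", RuntimeWarning)
        return -math.inf
    return m * math.log(RSS / m) + 2 * k


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square error between aligned vectors."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


# ---------------------------------------------------------------------------
# proliferation-law fitting on control growth curves


def growth_curve(model_id: str, theta: Sequence[float], N0: float,
                 times: Sequence[float], N_max: float = 100.0) -> np.ndarray:
    """Drug-free growth curve N(t) of one candidate law.

    Closed forms for the exponential, logistic and Gompertz laws; the
    Hill law (theta = (beta, n)) is integrated numerically.
    """
    times = np.asarray(times, dtype=float)
    beta = float(theta[0])
    if model_id == "exponential":
        return N0 * np.exp(beta * times)
    if model_id == "logistic":
        return N_max / (1.0 + (N_max - N0) / N0 * np.exp(-beta * times))
    if model_id == "gompertz":
        return N_max * (N0 / N_max) ** np.exp(-beta * times)
    if model_id == "hill":
        n = float(theta[1])
        from scipy.integrate import solve_ivp
        uniq, inv = np.unique(times, return_inverse=True)
        sol = solve_ivp(
            lambda t, y: beta * (1.0 - (max(y[0], 0.0) / N_max) ** n) * y[0],
            (0.0, float(uniq.max()) if uniq.size else 1.0), [N0],
            t_eval=uniq, rtol=1e-8, atol=1e-10)
        return sol.y[0][inv]
    raise ValueError(f"unknown proliferation model {model_id!r}")


_CANDIDATES = {
    "exponential": ([0.02], [(1e-4, 1.0)]),
    "logistic": ([0.02], [(1e-4, 1.0)]),
    "gompertz": ([0.01], [(1e-4, 1.0)]),
    "hill": ([0.02, 2.0], [(1e-4, 1.0), (0.2, 10.0)]),
}


@dataclass(frozen=True)
class ModelComparisonRecord:
    model_id: str
    regime: str              # "shared" or "per_seeding"
    k: int                   # free parameters entering each seeding's AIC
    m: int                   # total observations
    RSS: float
    mean_AIC: float
    converged: bool

    def __post_init__(self):
        if self.m <= self.k:
            raise ValueError("need more observations than parameters")
        if self.RSS < 0:
            raise ValueError("RSS must be >= 0")


@dataclass
class ProliferationFit:
    """All candidate-law fits on control data, both calibration regimes."""

    records: list[ModelComparisonRecord]
    thetas: dict             # (model_id, regime) -> theta or {seeding: theta}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def best(self, regime: str = "per_seeding") -> ModelComparisonRecord:
        cands = [r for r in self.records if r.regime == regime]
        return min(cands, key=lambda r: r.mean_AIC)

    def fitted_prolif(self, model_id: str | None = None,
                      seeding: float | None = None) -> ProliferationParams:
        """Fitted parameters of the selected law (per-seeding regime)."""
        if model_id is None:
            model_id = self.best().model_id
        theta = self.thetas[(model_id, "per_seeding")]
        if isinstance(theta, dict):
            theta = theta[seeding] if seeding is not None \
                else next(iter(theta.values()))
        n = theta[1] if len(theta) > 1 else 1.0
        return ProliferationParams(model_id=model_id, beta=theta[0], n=n)


def _fit_one_curve(model_id, groups, shared: bool):
    """Least-squares fit of one law; *groups* is {seeding: (times, obs)}."""
    guess, bounds = _CANDIDATES[model_id]
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]

    def residuals(theta, items):
        res = []
        for seeding, (times, obs) in items:
            pred = growth_curve(model_id, theta, seeding, times)
            res.append(pred - obs)
        return np.concatenate(res)

    if shared:
        sol = optimize.least_squares(residuals, guess, bounds=(lo, hi),
                                     args=(list(groups.items()),))
        return {s: sol.x for s in groups}, sol.success
    thetas, ok = {}, True
    for seeding, data in groups.items():
        sol = optimize.least_squares(residuals, guess, bounds=(lo, hi),
                                     args=([(seeding, data)],))
        thetas[seeding] = sol.x
        ok = ok and sol.success
    return thetas, ok


def fit_proliferation(control: ObservationSet,
                      candidates: Sequence[str] | None = None
                      ) -> ProliferationFit:
    """Fit every candidate growth law to control curves and rank by mean AIC.

    Both calibration regimes are evaluated: one shared theta across all
    seeding densities, and one theta per seeding density.  The mean AIC
    is the arithmetic mean of the per-seeding least-squares AIC values.
    """
    if candidates is None:
        candidates = list(_CANDIDATES)
    df = control.data
    if not np.isfinite(df["density_pct"]).all():
        raise ValueError("non-finite densities in control data")
    if "seeding_pct" not in df.columns:
        raise ValueError("control data needs a seeding_pct column")
    groups = {}
    for seeding, sub in df.groupby("seeding_pct"):
        times = sub["time_h"].to_numpy(dtype=float)
        obs = sub["density_pct"].to_numpy(dtype=float)
        if len(np.unique(times)) < 2:
            raise ValueError(f"seeding {seeding}: need >= 2 time points")
        groups[float(seeding)] = (times, obs)

    records, thetas = [], {}
    for model_id in candidates:
        k = len(_CANDIDATES[model_id][0])
        for regime, shared in (("shared", True), ("per_seeding", False)):
            fitted, ok = _fit_one_curve(model_id, groups, shared)
            aics, total_rss, total_m = [], 0.0, 0
            for seeding, (times, obs) in groups.items():
                pred = growth_curve(model_id, fitted[seeding], seeding, times)
                rss = float(np.sum((pred - obs) ** 2))
                m = obs.size
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    aics.append(aic(max(rss, 1e-300), k, m))
                total_rss += rss
                total_m += m
            records.append(ModelComparisonRecord(
                model_id=model_id, regime=regime, k=k, m=total_m,
                RSS=total_rss, mean_AIC=float(np.mean(aics)), converged=ok))
            thetas[(model_id, regime)] = (fitted if not shared
                                          else next(iter(fitted.values())))
    return ProliferationFit(records=records, thetas=thetas)


# ---------------------------------------------------------------------------
# PSM1D calibration


@dataclass(frozen=True)
class FreeParameter:
    name: str
    lower: float
    upper: float
    guess: float


def free_parameter_spec(topology: Topology, drug: DrugParams,
                        calibrate_dose: bool = False) -> list[FreeParameter]:
    """The free parameters of one topology, with bounds and initial guesses.

    The switching baselines are always free.  The drug decay rate is free
    when at least one drug effect is active (otherwise the drug level
    feeds nothing and it is unidentifiable).  The input dose is fixed at
    the experimental value by default — it enters the dynamics only
    through the saturating memory input, where it is structurally
    confounded with the memory sensitivities — but can be freed within
    +/-50 % of the experimental dose via ``calibrate_dose``.  Each active
    effect contributes its memory sensitivity and reset speed.
    """
    spec = [
        FreeParameter("alpha_ST0", 1e-4, 0.5, 0.02),
        FreeParameter("alpha_TS0", 1e-4, 0.5, 0.02),
    ]
    if any(topology.flags):
        spec.append(FreeParameter("k_d", 0.01, 5.0, drug.D_input / 24.0))
        if calibrate_dose:
            spec.append(FreeParameter("D_input", 0.5 * drug.D_input,
                                      1.5 * drug.D_input, drug.D_input))
    for flag, rate in zip(topology.flags, ("ST", "TS", "beta")):
        if flag:
            spec.append(FreeParameter(f"mu_{rate}", 1e-4, 1.0, 0.05))
            spec.append(FreeParameter(f"lambda_{rate}", 1e-3, 1.0, 0.02))
    return spec


def _events_of(schedule: RegimenSchedule):
    return [(e.time_h, e.dose, e.wash) for e in schedule.events]


def _ST_on_grid_1d(pvec, flags, kd, D50, kappa, events, horizon, obs,
                   S0, T0, dt):
    """(S, T) at the sorted observation times; left limits at event
    times.  Lean fixed-step path used inside cost functions."""
    y = np.array([S0, T0, 0.0, 0.0, 0.0])
    D = 0.0
    S_res = np.empty(obs.size)
    T_res = np.empty(obs.size)
    oi = 0
    while oi < obs.size and obs[oi] <= 1e-12:
        S_res[oi], T_res[oi] = S0, T0
        oi += 1
    boundaries = sorted({0.0, horizon, *(t for t, _, _ in events)})
    events_at = {t: (dose, wash) for t, dose, wash in events}
    for t_a, t_b in zip(boundaries[:-1], boundaries[1:]):
        ev = events_at.get(t_a)
        if ev is not None:
            dose, wash = ev
            if wash:
                D = 0.0
            D += dose
            if dose > 0:
                y[0] *= kappa
        segs = [(t_a, t_b, D)]
        if D > 0 and kd > 0:
            tc = t_a + D / kd
            if tc < t_b - 1e-12:
                segs = [(t_a, tc, D), (tc, t_b, 0.0)]
        for s_a, s_b, D0 in segs:
            ts, ys = _fast.integrate_segment_1d(y, s_a, s_b, dt, D0, kd, D50,
                                                pvec, *flags)
            hi = oi
            while hi < obs.size and obs[hi] <= s_b + 1e-12:
                hi += 1
            if hi > oi:
                S_res[oi:hi] = np.interp(obs[oi:hi], ts, ys[:, 0])
                T_res[oi:hi] = np.interp(obs[oi:hi], ts, ys[:, 1])
                oi = hi
            y = ys[-1]
        D = max(0.0, D - kd * (t_b - t_a))
    return S_res, T_res


class PSM1DCostFunction:
    """Penalized least-squares cost of one topology across regimens.

    cost(theta) = sum_r w_r sum_obs (model - observation)^2
                  + penalty_weight * sum_j bound_violation_j^2

    One parameter vector is shared by the simulations of all regimens.
    S and T observation rows are matched to the model compartments,
    N rows to their sum.  Simulation failures inside the cost return a
    large finite sentinel so the optimizer can continue.
    """

    def __init__(self, datasets: ObservationSet,
                 topology: Topology, prolif: ProliferationParams,
                 drug: DrugParams,
                 regimens: Mapping[str, RegimenSchedule] | None = None,
                 weights: Mapping[str, float] | None = None,
                 penalty_weight: float = 1e4, dt: float = 0.1,
                 N0: float | None = None, calibrate_dose: bool = False):
        self.topology = topology
        self.prolif = prolif
        self.drug = drug
        self.spec = free_parameter_spec(topology, drug, calibrate_dose)
        self.names = [p.name for p in self.spec]
        self.lower = np.array([p.lower for p in self.spec])
        self.upper = np.array([p.upper for p in self.spec])
        self.guess = np.array([p.guess for p in self.spec])
        self.penalty_weight = penalty_weight
        self.dt = dt
        if regimens is None:
            regimens = three_regimens(drug.drug_id, drug.D_input)
        present = datasets.regimens()
        self.regimens = {k: v for k, v in regimens.items() if k in present}
        if not self.regimens:
            raise ValueError("no overlap between datasets and regimen schedules")
        self.weights = {k: 1.0 for k in self.regimens}
        if weights:
            self.weights.update(weights)
        # per regimen: observation times and one matrix per observable
        self._obs: dict[str, tuple[np.ndarray, dict[str, np.ndarray]]] = {}
        df = datasets.data.copy()
        if "compartment" not in df.columns:
            df["compartment"] = "N"
        for name in self.regimens:
            sub = df[df["regimen"] == name]
            t = np.sort(sub["time_h"].unique()).astype(float)
            mats = {}
            for comp, csub in sub.groupby("compartment"):
                mat = csub.pivot_table(index="time_h", columns="replicate",
                                       values="density_pct")
                mats[comp] = mat.reindex(t).to_numpy(dtype=float)
            self._obs[name] = (t, mats)
        if N0 is None:
            at0 = df[df["time_h"] <= 1e-9]
            if len(at0):
                per_rep = at0.groupby(["regimen", "replicate", "compartment"])[
                    "density_pct"].mean().groupby(
                        ["regimen", "replicate"]).sum()
                N0 = float(per_rep.mean())
            else:
                N0 = 10.0
        self.N0 = N0

    # -- parameter plumbing ----------------------------------------------

    def to_params(self, theta: Sequence[float]) -> PSM1DParams:
        """Materialize a full parameter bundle from a free-parameter vector."""
        d = dict(zip(self.names, np.asarray(theta, dtype=float)))
        inactive = MemoryParams(mu=0.0, lambda_=1.0)

        def mem(rate):
            if f"mu_{rate}" in d:
                return MemoryParams(mu=d[f"mu_{rate}"],
                                    lambda_=d[f"lambda_{rate}"])
            return inactive

        drug = DrugParams(drug_id=self.drug.drug_id,
                          D_input=d.get("D_input", self.drug.D_input),
                          k_d=d.get("k_d", self.drug.k_d),
                          D_50=self.drug.D_50, kappa=self.drug.kappa)
        return PSM1DParams(
            prolif=self.prolif, drug=drug,
            switch=SwitchRates(alpha_ST0=d["alpha_ST0"],
                               alpha_TS0=d["alpha_TS0"]),
            memory=MemoryBank(ST=mem("ST"), TS=mem("TS"), beta=mem("beta")),
            topology=self.topology)

    def _penalty(self, theta: np.ndarray) -> float:
        viol = np.maximum(self.lower - theta, 0.0) ** 2 \
            + np.maximum(theta - self.upper, 0.0) ** 2
        return self.penalty_weight * float(viol.sum())

    def predict(self, theta: Sequence[float], regimen: str
                ) -> tuple[np.ndarray, np.ndarray]:
        """Model (S, T) at the regimen's observation times for this theta."""
        theta = np.asarray(theta, dtype=float)
        d = dict(zip(self.names, theta))
        kd = d.get("k_d", self.drug.k_d)
        dose = d.get("D_input", self.drug.D_input)
        a_st0, a_ts0 = d["alpha_ST0"], d["alpha_TS0"]
        pr = self.prolif
        pvec = np.array([
            pr.beta, pr.n, pr.N_max, pr.code, int(pr.hill_rational),
            a_st0, a_ts0,
            d.get("mu_ST", 0.0), d.get("lambda_ST", 1.0),
            d.get("mu_TS", 0.0), d.get("lambda_TS", 1.0),
            d.get("mu_beta", 0.0), d.get("lambda_beta", 1.0),
        ])
        flags = tuple(int(f) for f in self.topology.flags)
        sched = self.regimens[regimen]
        # a calibrated dose enters through the events: rescale scheduled doses
        scale = dose / self.drug.D_input
        events = [(t, dz * scale, w) for t, dz, w in _events_of(sched)]
        t_obs, _ = self._obs[regimen]
        tot = a_st0 + a_ts0
        s_frac = a_ts0 / tot if tot > 0 else 1.0
        return _ST_on_grid_1d(pvec, flags, kd, self.drug.D_50,
                              self.drug.kappa, events, sched.horizon, t_obs,
                              self.N0 * s_frac, self.N0 * (1 - s_frac),
                              self.dt)

    def residuals(self, theta: Sequence[float]) -> np.ndarray:
        """Weighted residual vector over all regimens and observables."""
        theta = np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)
        blocks = []
        for name in self.regimens:
            t_obs, mats = self._obs[name]
            w = math.sqrt(self.weights[name])
            try:
                S, T = self.predict(theta, name)
            except Exception:
                S = T = None
            for comp, obs_mat in mats.items():
                if S is None or not (np.all(np.isfinite(S))
                                     and np.all(np.isfinite(T))):
                    blocks.append(np.full(obs_mat.size, _SENTINEL_RESID))
                    continue
                model = {"S": S, "T": T, "N": S + T}[comp]
                resid = (obs_mat - model[:, None]) * w
                blocks.append(np.nan_to_num(resid.ravel(), nan=0.0))
        return np.concatenate(blocks)

    def __call__(self, theta: Sequence[float]) -> float:
        theta = np.asarray(theta, dtype=float)
        pen = self._penalty(theta)
        r = self.residuals(theta)
        if np.any(r >= _SENTINEL_RESID):
            return _SENTINEL_COST + pen
        return float(np.dot(r, r)) + pen

    def rmse_per_regimen(self, theta: Sequence[float]) -> dict[str, float]:
        """RMSE of the fitted total density against the replicate-mean
        N curve (sum of S and T rows for compartment-resolved data)."""
        out = {}
        theta = np.asarray(theta, dtype=float)
        for name in self.regimens:
            t_obs, mats = self._obs[name]
            S, T = self.predict(theta, name)
            if "N" in mats:
                obs_N = np.nanmean(mats["N"], axis=1)
            else:
                obs_N = sum(np.nanmean(mats[c], axis=1)
                            for c in ("S", "T") if c in mats)
            out[name] = rmse(S + T, obs_N)
        return out


@dataclass
class CalibrationResult:
    """Outcome of a multi-start penalized least-squares calibration."""

    theta: dict[str, float]
    params: PSM1DParams | PSM2DParams
    cost: float
    rmse_per_regimen: dict[str, float]
    converged: bool
    seed: int
    n_starts: int
    bounds: dict[str, tuple[float, float]]
    initial_guess: dict[str, float]
    start_costs: list[float] = field(default_factory=list)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(list(self.rmse_per_regimen.values())))


def _multistart_least_squares(residuals_fn, guess, lower, upper, n_starts,
                              seed, stop_cost=1e-12):
    """Multi-start TRF least squares in log-parameter space."""
    llo, lhi = np.log(lower), np.log(upper)
    rng = np.random.default_rng(seed)
    starts = [np.clip(np.log(np.asarray(guess, dtype=float)), llo, lhi)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(llo, lhi))

    def fn(z):
        return residuals_fn(np.exp(z))

    best_x, best_cost, start_costs, any_ok = None, math.inf, [], False
    for x0 in starts:
        try:
            sol = optimize.least_squares(fn, x0, bounds=(llo, lhi),
                                         method="trf", x_scale="jac",
                                         ftol=3e-16, xtol=3e-16, gtol=None)
            sol = optimize.least_squares(fn, sol.x, bounds=(llo, lhi),
                                         method="trf", x_scale="jac",
                                         ftol=3e-16, xtol=3e-16, gtol=None)
        except Exception:
            start_costs.append(math.inf)
            continue
        c = 2.0 * float(sol.cost)
        start_costs.append(c)
        any_ok = True
        if c < best_cost:
            best_cost, best_x = c, sol.x
        if best_cost < stop_cost:
            break
    if best_x is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed: {start_costs}")
    return np.exp(best_x), best_cost, start_costs, any_ok


def _multistart_powell(cost_fn, guess, lower, upper, n_starts, seed):
    """Multi-start bounded Powell search on the scalar cost (log space)."""
    llo, lhi = np.log(lower), np.log(upper)
    rng = np.random.default_rng(seed)
    starts = [np.clip(np.log(np.asarray(guess, dtype=float)), llo, lhi)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(llo, lhi))
    best, start_costs = None, []
    for x0 in starts:
        try:
            sol = optimize.minimize(lambda z: cost_fn(np.exp(z)), x0,
                                    method="Powell",
                                    bounds=list(zip(llo, lhi)),
                                    options={"xtol": 1e-12, "ftol": 1e-14})
        except Exception:
            start_costs.append(math.inf)
            continue
        start_costs.append(float(sol.fun))
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed: {start_costs}")
    return np.exp(best.x), float(best.fun), start_costs, bool(best.success)


def calibrate_psm1d(datasets: ObservationSet, topology: Topology,
                    prolif: ProliferationParams, drug: DrugParams,
                    regimens: Mapping[str, RegimenSchedule] | None = None,
                    weights: Mapping[str, float] | None = None,
                    bounds: Mapping[str, tuple[float, float]] | None = None,
                    initial_guess: Mapping[str, float] | None = None,
                    n_starts: int = 10, seed: int = 0,
                    penalty_weight: float = 1e4, dt: float = 0.1,
                    calibrate_dose: bool = False,
                    optimizer: str = "trf") -> CalibrationResult:
    """Fit the free parameters of one topology to multi-regimen data.

    Proliferation parameters must come from a prior control-data fit and
    stay fixed here; ``drug`` supplies the experimental dose, the memory
    half-saturation D_50 and the surviving fraction kappa.  Multi-start
    bounded search in log-parameter space; deterministic given *seed*.
    """
    cost = PSM1DCostFunction(datasets, topology, prolif, drug,
                             regimens=regimens, weights=weights,
                             penalty_weight=penalty_weight, dt=dt,
                             calibrate_dose=calibrate_dose)
    if bounds:
        for i, name in enumerate(cost.names):
            if name in bounds:
                cost.lower[i], cost.upper[i] = bounds[name]
    guess = cost.guess.copy()
    if initial_guess:
        for i, name in enumerate(cost.names):
            if name in initial_guess:
                guess[i] = initial_guess[name]
    if optimizer == "trf":
        theta, best_cost, start_costs, ok = _multistart_least_squares(
            cost.residuals, guess, cost.lower, cost.upper, n_starts, seed)
        best_cost += cost._penalty(theta)
    elif optimizer == "powell":
        theta, best_cost, start_costs, ok = _multistart_powell(
            cost, guess, cost.lower, cost.upper, n_starts, seed)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    theta = np.clip(theta, cost.lower, cost.upper)
    return CalibrationResult(
        theta=dict(zip(cost.names, (float(v) for v in theta))),
        params=cost.to_params(theta),
        cost=float(best_cost),
        rmse_per_regimen=cost.rmse_per_regimen(theta),
        converged=ok,
        seed=seed, n_starts=n_starts,
        bounds={n: (float(l), float(u))
                for n, l, u in zip(cost.names, cost.lower, cost.upper)},
        initial_guess=dict(zip(cost.names, (float(v) for v in guess))),
        start_costs=start_costs)


# ---------------------------------------------------------------------------
# topology grid


@dataclass
class TopologyGridResult:
    """Topology x regimen RMSE matrix with per-regimen best topology."""

    grid: pd.DataFrame                       # index: topology index
    labels: dict[int, str]                   # index -> "(+,-,=)" annotation
    best_per_regimen: dict[str, int]
    calibrations: dict[int, CalibrationResult]

    def annotated(self) -> pd.DataFrame:
        out = self.grid.copy()
        out.insert(0, "topology", [self.labels[i] for i in out.index])
        return out

    def to_csv(self, path) -> None:
        self.annotated().to_csv(path)

    def scaled(self) -> pd.DataFrame:
        """Grid min-max scaled over all cells (heatmap convention)."""
        v = self.grid.to_numpy(dtype=float)
        lo, hi = np.nanmin(v), np.nanmax(v)
        return (self.grid - lo) / (hi - lo) if hi > lo else self.grid * 0.0


def topology_grid(datasets: ObservationSet, prolif: ProliferationParams,
                  drug: DrugParams,
                  topologies: Sequence[Topology] | None = None,
                  regimens: Mapping[str, RegimenSchedule] | None = None,
                  n_starts: int = 6, seed: int = 0, dt: float = 0.1,
                  **kwargs) -> TopologyGridResult:
    """Calibrate every topology and tabulate per-regimen RMSE.

    Each topology is calibrated once on all regimens combined (one
    shared parameter vector); the grid holds the per-regimen RMSE of
    that fit, with failed calibrations marked as missing cells.
    """
    if topologies is None:
        topologies = all_topologies()
    rows, labels, calibs = {}, {}, {}
    root = np.random.SeedSequence(seed)
    for topo, child in zip(topologies, root.spawn(len(topologies))):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        labels[topo.index] = topo.label()
        try:
            res = calibrate_psm1d(datasets, topo, prolif, drug,
                                  regimens=regimens, n_starts=n_starts,
                                  seed=sub_seed, dt=dt, **kwargs)
            calibs[topo.index] = res
            rows[topo.index] = res.rmse_per_regimen
        except Exception:
            rows[topo.index] = {}
    grid = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    grid.index.name = "topology_index"
    best = {c: int(grid[c].idxmin()) for c in grid.columns
            if grid[c].notna().any()}
    return TopologyGridResult(grid=grid, labels=labels,
                              best_per_regimen=best, calibrations=calibs)


# ---------------------------------------------------------------------------
# PSM2D coupling estimation


def _N_on_grid_2d(params2: PSM2DParams, coupling: CouplingParams,
                  schedule: RegimenSchedule, obs: np.ndarray,
                  N0: float, dt: float) -> np.ndarray:
    """Lean fixed-step two-drug N(t) on the observation grid."""
    from .psm2d import initial_state_psm2d
    p2 = replace(params2, coupling=coupling)
    pvec = _param_vector_2d(p2)
    flags = _topo_flags_2d(p2)
    drugs = {DrugId.A: p2.drug_A.drug, DrugId.N: p2.drug_N.drug}
    y0 = initial_state_psm2d(p2, N0=N0)
    y = y0[[0, 1, 2, 5, 6, 7, 8, 9, 10, 11]].copy()
    levels = {DrugId.A: 0.0, DrugId.N: 0.0}
    res = np.empty(obs.size)
    oi = 0
    while oi < obs.size and obs[oi] <= 1e-12:
        res[oi] = N0
        oi += 1
    boundaries = sorted({0.0, schedule.horizon,
                         *(e.time_h for e in schedule.events)})
    events_at = {e.time_h: e for e in schedule.events}
    for t_a, t_b in zip(boundaries[:-1], boundaries[1:]):
        ev = events_at.get(t_a)
        if ev is not None:
            if ev.wash:
                levels = {k: 0.0 for k in levels}
            levels[ev.drug_id] += ev.dose
            if ev.dose > 0:
                kappa = drugs[ev.drug_id].kappa
                for comp in DEFAULT_KILL_SETS[ev.drug_id]:
                    y[0 if comp == "S_A" else 1] *= kappa
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
            ts, ys = _fast.integrate_segment_2d(
                y, s_a, s_b, dt, DA_s, kdA if DA_s > 0 else 0.0,
                DN_s, kdN if DN_s > 0 else 0.0, pvec, *flags)
            hi = oi
            while hi < obs.size and obs[hi] <= s_b + 1e-12:
                hi += 1
            if hi > oi:
                Nline = ys[:, 0] + ys[:, 1] + ys[:, 2]
                res[oi:hi] = np.interp(obs[oi:hi], ts, Nline)
                oi = hi
            y = ys[-1]
        levels[DrugId.A] = max(0.0, DA0 - kdA * (t_b - t_a))
        levels[DrugId.N] = max(0.0, DN0 - kdN * (t_b - t_a))
    return res


def calibrate_coupling(alternated_data: ObservationSet,
                       params2: PSM2DParams,
                       schedule: RegimenSchedule,
                       regimen: str = "Alternated",
                       bounds: tuple[tuple[float, float], ...] = ((1e-3, 10.0),
                                                                  (1e-3, 2.0)),
                       initial_guess: tuple[float, float] = (1.0, 0.1),
                       n_starts: int = 8, seed: int = 0, dt: float = 0.1
                       ) -> CalibrationResult:
    """Estimate (mu_TSN, lambda_TSN) with the one-drug fits frozen.

    Two-parameter bounded fit minimizing the squared error of the
    coupled model's total density against alternated-regimen data.
    """
    sub = alternated_data.subset(regimen)
    if "compartment" in sub.columns:
        sub = sub[sub["compartment"] == "N"]
    if sub.empty:
        raise ValueError(f"no total-density observations for regimen {regimen!r}")
    t_obs = np.sort(sub["time_h"].unique()).astype(float)
    obs_mat = sub.pivot_table(index="time_h", columns="replicate",
                              values="density_pct").loc[t_obs].to_numpy()
    at0 = sub[sub["time_h"] <= 1e-9]
    N0 = float(at0["density_pct"].mean()) if len(at0) else 10.0
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])

    def residuals(theta):
        mu, lam = np.clip(theta, lower, upper)
        try:
            pred = _N_on_grid_2d(params2,
                                 CouplingParams(mu_TSN=mu, lambda_TSN=lam),
                                 schedule, t_obs, N0, dt)
        except Exception:
            return np.full(obs_mat.size, _SENTINEL_RESID)
        if not np.all(np.isfinite(pred)):
            return np.full(obs_mat.size, _SENTINEL_RESID)
        return np.nan_to_num((obs_mat - pred[:, None]).ravel(), nan=0.0)

    theta, best_cost, start_costs, ok = _multistart_least_squares(
        residuals, np.asarray(initial_guess, dtype=float), lower, upper,
        n_starts, seed)
    mu, lam = np.clip(theta, lower, upper)
    coupling = CouplingParams(mu_TSN=float(mu), lambda_TSN=float(lam))
    fitted = replace(params2, coupling=coupling)
    pred = _N_on_grid_2d(params2, coupling, schedule, t_obs, N0, dt)
    return CalibrationResult(
        theta={"mu_TSN": float(mu), "lambda_TSN": float(lam)},
        params=fitted, cost=float(best_cost),
        rmse_per_regimen={regimen: rmse(pred, np.nanmean(obs_mat, axis=1))},
        converged=ok, seed=seed, n_starts=n_starts,
        bounds={"mu_TSN": tuple(map(float, bounds[0])),
                "lambda_TSN": tuple(map(float, bounds[1]))},
        initial_guess={"mu_TSN": float(initial_guess[0]),
                       "lambda_TSN": float(initial_guess[1])},
        start_costs=start_costs)
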