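"""Post-simulation analytics: equilibria, relaxation times, growth
decomposition and the experimental density-change statistic.

Away from drug inputs the sensitive *fraction* s = S/N obeys the scalar
linear ODE  ds/dt = alpha_TS - (alpha_TS + alpha_ST) s, independent of
the proliferation law, so the population relaxes exponentially (rate
alpha_ST + alpha_TS) to the equilibrium proportions
100 * (alpha_TS, alpha_ST) / (alpha_ST + alpha_TS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import effective_rates
from .params import PSM1DParams
from .trajectory import Trajectory

__all__ = [
    "equilibrium_proportions",
    "EquilibriumReport",
    "time_to_equilibrium",
    "GrowthDecomposition",
    "growth_decomposition",
    "density_change",
]


def equilibrium_proportions(alpha_ST: float, alpha_TS: float
                            ) -> tuple[float, float]:
    """Drug-free equilibrium (S_eq, T_eq) in % of the population."""
    if alpha_ST < 0 or alpha_TS < 0:
        raise ValueError("switching rates must be >= 0")
    tot = alpha_ST + alpha_TS
    if tot <= 0:
        raise ValueError("equilibrium undefined when both rates are zero")
    return 100.0 * alpha_TS / tot, 100.0 * alpha_ST / tot


@dataclass(frozen=True)
class EquilibriumReport:
    S_eq: float
    T_eq: float
    time_to_equilibrium: float | None
    tolerance: float

    def __post_init__(self):
        if abs(self.S_eq + self.T_eq - 100.0) > 1e-9:
            raise ValueError("equilibrium proportions must sum to 100")


def time_to_equilibrium(traj: Trajectory, S_eq: float, tol: float = 1.0,
                        from_time: float = 0.0) -> float | None:
    """First time after which the sensitive share stays within *tol* of S_eq.

    ``S_eq`` and ``tol`` are absolute percentages of the population.
    With a treatment schedule, pass the last drug-input time as
    ``from_time`` to measure the reset delay from the end of treatment.
    Returns time relative to ``from_time``, or ``None`` if the share
    never settles within the stored horizon.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    N = traj.N
    if np.any(N <= 0):
        raise ValueError("trajectory must have N > 0 throughout")
    sens = traj.column(traj.density_columns[0])
    share = 100.0 * sens / N
    dev = np.abs(share - S_eq)
    t = traj.times
    mask = t >= from_time - 1e-12
    t, dev = t[mask], dev[mask]
    if dev.size == 0 or dev[-1] >= tol:
        return None
    inside = dev < tol
    # last index at which the share is still outside the band
    outside_idx = np.nonzero(~inside)[0]
    if outside_idx.size == 0:
        return 0.0
    j = outside_idx[-1]
    if j + 1 >= t.size:
        return None
    # linear interpolation of the band entry between samples j and j+1
    d0, d1 = dev[j], dev[j + 1]
    w = 0.0 if d0 == d1 else (d0 - tol) / (d0 - d1)
    t_cross = t[j] + w * (t[j + 1] - t[j])
    return float(max(0.0, t_cross - from_time))


@dataclass(frozen=True)
class GrowthDecomposition:
    """Per-compartment split of the growth rate into proliferation and
    net phenotypic switching (both %/h); the two components sum to the
    compartment's total derivative at every stored point."""

    times: np.ndarray
    proliferation: pd.DataFrame   # one column per compartment, P * X
    switching: pd.DataFrame       # in-flux minus out-flux per compartment

    def total(self) -> pd.DataFrame:
        return self.proliferation + self.switching

    def per_capita(self) -> pd.DataFrame:
        """Total growth rate divided by the compartment density (1/h)."""
        return self.total() / self._densities.replace(0.0, np.nan)

    def magnitude_ratio(self) -> pd.Series:
        """Median |switching| / |proliferation| per compartment."""
        num = self.switching.abs().median()
        den = self.proliferation.abs().median()
        return num / den.replace(0.0, np.nan)


def growth_decomposition(traj: Trajectory, params: PSM1DParams
                         ) -> GrowthDecomposition:
    """Recompute, at every stored state, the proliferation component
    P(N) * X and the net switching component of each compartment's growth."""
    from . import _fast

    S = traj.column("S")
    T = traj.column("T")
    N = S + T
    a_st = np.empty_like(S)
    a_ts = np.empty_like(S)
    P = np.empty_like(S)
    for i in range(S.size):
        ast, ats, beta = effective_rates(
            params.topology, params.switch, params.prolif,
            traj.column("M_ST")[i], traj.column("M_TS")[i],
            traj.column("M_beta")[i])
        a_st[i], a_ts[i] = ast, ats
        P[i] = (_fast.prolif_rate(params.prolif.code,
                                  int(params.prolif.hill_rational), beta,
                                  params.prolif.n, params.prolif.N_max, N[i])
                if N[i] > 0 else 0.0)
    P = np.where(N > 0, P, 0.0)
    prolif = pd.DataFrame({"S": P * S, "T": P * T})
    switch = pd.DataFrame({"S": a_ts * T - a_st * S, "T": a_st * S - a_ts * T})
    dec = GrowthDecomposition(times=traj.times.copy(), proliferation=prolif,
                              switching=switch)
    object.__setattr__(dec, "_densities", pd.DataFrame({"S": S, "T": T}))
    return dec


def density_change(CD_t1: float, CD_t2: float) -> float:
    """Percent change in cell density between two measurements."""
    if CD_t1 <= 0:
        raise ValueError("CD_t1 must be > 0")
    return (CD_t2 - CD_t1) / CD_t1 * 100.0
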