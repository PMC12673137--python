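"""Synthetic benchmark data: control growth curves, one-drug regimen
time courses and two-drug alternated time courses.

The generators emulate the structure of clonogenicity measurements
(fraction of dish area occupied, sampled on a 24-h grid, a few noisy
replicates per condition) from known ground-truth parameters, so the
full pipeline — calibration, topology comparison, coupling estimation —
can be exercised and benchmarked without any external data.  Every
dataset carries a provenance block recording the generating parameters,
topology, noise scale and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import simulate_psm1d
from .params import (DrugId, DrugParams, MemoryBank, MemoryParams,
                     PSM1DParams, PSM2DParams, ProliferationParams,
                     SwitchRates, Topology, CouplingParams, _clean,
                     params_to_json)
from .psm2d import simulate_psm2d
from .regimens import RegimenSchedule, three_regimens, alternated, repeated

__all__ = [
    "NoiseKind", "NoiseModel", "ObservationSet",
    "default_params_A", "default_params_N", "default_params_2d",
    "generate_control_growth", "generate_regimen_data", "generate_psm2d_data",
    "random_psm1d_params",
]

OBS_COLUMNS = ["time_h", "regimen", "replicate", "density_pct", "seeding_pct"]

#: optional column tagging what a density row measures: total density N or
#: a resolved compartment.  Treatment experiments resolve the sensitive /
#: tolerant split at each observation day from the density drop caused by
#: the next drug input (killed fraction = sensitive, survivors = tolerant).
COMPARTMENT_VALUES = ("N", "S", "T", "S_A", "S_N")


class NoiseKind(str, Enum):
    ADDITIVE_GAUSSIAN_TRUNCATED = "additive_gaussian_truncated"
    MULTIPLICATIVE_LOGNORMAL = "multiplicative_lognormal"


@dataclass(frozen=True)
class NoiseModel:
    """Replicate observation noise.

    The default, additive Gaussian with sigma = 1 % of dish area
    truncated at zero, mirrors the magnitude of replicate scatter in
    plate-based density measurements.
    """

    kind: NoiseKind = NoiseKind.ADDITIVE_GAUSSIAN_TRUNCATED
    sigma: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "kind", NoiseKind(self.kind))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        if self.kind is NoiseKind.ADDITIVE_GAUSSIAN_TRUNCATED:
            noisy = values + rng.normal(0.0, self.sigma, size=values.shape)
        else:
            noisy = values * rng.lognormal(0.0, self.sigma, size=values.shape)
        return np.clip(noisy, 0.0, 100.0)


@dataclass
class ObservationSet:
    """Long-format density observations plus generation provenance."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(OBS_COLUMNS[:4]) - set(self.data.columns)
        if missing:
            raise ValueError(f"observation data missing columns {sorted(missing)}")
        dens = self.data["density_pct"]
        if not np.isfinite(dens).all():
            raise ValueError("non-finite densities in observation set")
        if (dens < 0).any() or (dens > 100).any():
            raise ValueError("densities must lie in [0, 100]")
        if "compartment" in self.data.columns:
            bad = set(self.data["compartment"]) - set(COMPARTMENT_VALUES)
            if bad:
                raise ValueError(f"unknown compartment labels {sorted(bad)}")

    def regimens(self) -> list[str]:
        return sorted(self.data["regimen"].unique())

    def subset(self, regimen: str) -> pd.DataFrame:
        return self.data[self.data["regimen"] == regimen]

    def mean_curve(self, regimen: str) -> pd.Series:
        """Replicate-averaged total density N indexed by time.

        Compartment-resolved rows are summed back to the total before
        averaging.
        """
        sub = self.subset(regimen)
        if "compartment" in sub.columns and set(sub["compartment"]) != {"N"}:
            per_rep = sub[sub["compartment"] != "N"].groupby(
                ["time_h", "replicate"])["density_pct"].sum()
            return per_rep.groupby("time_h").mean()
        return sub.groupby("time_h")["density_pct"].mean()

    def to_csv(self, path, provenance_path=None) -> None:
        self.data.to_csv(path, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(_clean(self.provenance), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# reference ground-truth parameter sets (synthetic study conditions)


def default_params_A() -> PSM1DParams:
    """Synthetic stand-in for a calibrated pro-apoptotic (TRAIL-like) drug.

    Chosen a priori on domain grounds: dish-level Hill growth with a
    low-density rate of 0.04/h; a drug-free switching equilibrium of
    80 % sensitive / 20 % tolerant relaxing on a ~3-day timescale; dose
    20 with the memory half-saturation at the dose; drug decay clearing
    the dish in about a day; the full topology (+,-,-) in which the drug
    promotes tolerance, blocks resensitization and slows proliferation,
    with a slow reset of the T->S inhibition.
    """
    return PSM1DParams(
        prolif=ProliferationParams(beta=0.04, n=2.0),
        drug=DrugParams(drug_id=DrugId.A, D_input=20.0, k_d=0.8, D_50=20.0),
        switch=SwitchRates(alpha_ST0=0.01, alpha_TS0=0.04),
        memory=MemoryBank(ST=MemoryParams(mu=0.05, lambda_=0.02),
                          TS=MemoryParams(mu=0.05, lambda_=0.01),
                          beta=MemoryParams(mu=0.05, lambda_=0.02)),
        topology=Topology.from_index(3),
    )


def default_params_N() -> PSM1DParams:
    """Synthetic stand-in for a calibrated pro-necroptotic (TBQ-like) drug:
    topology (+,=,-) (promotes tolerance and slows proliferation, leaves
    resensitization alone) with markedly slower memory reset."""
    return PSM1DParams(
        prolif=ProliferationParams(beta=0.04, n=2.0),
        drug=DrugParams(drug_id=DrugId.N, D_input=10.0, k_d=0.4, D_50=10.0),
        switch=SwitchRates(alpha_ST0=0.008, alpha_TS0=0.03),
        memory=MemoryBank(ST=MemoryParams(mu=0.04, lambda_=0.005),
                          TS=MemoryParams(mu=0.0, lambda_=0.01),
                          beta=MemoryParams(mu=0.03, lambda_=0.005)),
        topology=Topology.from_index(2),
    )


def default_params_2d(coupling: CouplingParams | None = None) -> PSM2DParams:
    """Coupled two-drug bundle from the two one-drug reference sets.

    The default coupling resets fast (lambda = 0.5/h) so the activated
    T -> S_N rate essentially tracks the pro-apoptotic drug concentration.
    """
    return PSM2DParams(drug_A=default_params_A(), drug_N=default_params_N(),
                       coupling=coupling or CouplingParams())


def random_psm1d_params(rng: np.random.Generator,
                        topology: Topology | None = None) -> PSM1DParams:
    """A random but plausible one-drug parameter draw for validation suites.

    Rates are drawn over the ranges the reference sets inhabit (growth
    0.01-0.06/h, switching 1e-3-0.1/h, memory charge up to 0.2/h with
    resets between hours and days); the topology is drawn uniformly
    unless given.
    """
    if topology is None:
        topology = Topology.from_index(int(rng.integers(1, 9)))

    def mem():
        return MemoryParams(mu=float(rng.uniform(0.0, 0.2)),
                            lambda_=float(rng.uniform(0.005, 0.5)))

    return PSM1DParams(
        prolif=ProliferationParams(beta=float(rng.uniform(0.01, 0.06)),
                                   n=float(rng.uniform(1.0, 3.0))),
        drug=DrugParams(drug_id=DrugId.A, D_input=20.0,
                        k_d=float(rng.uniform(0.2, 2.0)), D_50=20.0),
        switch=SwitchRates(alpha_ST0=float(rng.uniform(1e-3, 0.1)),
                           alpha_TS0=float(rng.uniform(1e-3, 0.1))),
        memory=MemoryBank(ST=mem(), TS=mem(), beta=mem()),
        topology=topology)


# ---------------------------------------------------------------------------
# generators


def _provenance(kind: str, noise: NoiseModel, seed, extra: dict) -> dict:
    return {"kind": kind, "noise": {"kind": noise.kind.value,
                                    "sigma": noise.sigma},
            "seed": seed, **extra}


def generate_control_growth(seedings: Sequence[float],
                            prolif: ProliferationParams,
                            times: Sequence[float],
                            noise: NoiseModel = NoiseModel(),
                            seed: int = 0,
                            replicates: int = 3) -> ObservationSet:
    """No-drug growth curves at several seeding densities.

    Integrates the chosen proliferation law from each seeding, samples it
    at *times* and applies truncated observation noise.  Densities are
    clamped to [0, 100].
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    records = []
    for seeding in seedings:
        if not 0.0 < seeding < 100.0:
            raise ValueError(f"seeding must lie in (0, 100), got {seeding}")
        params = PSM1DParams(prolif=prolif, switch=SwitchRates(0.0, 0.0),
                             topology=Topology.from_index(1))
        traj = simulate_psm1d(params, RegimenSchedule(horizon=float(times.max() or 1.0)),
                              y0=np.array([seeding, 0.0]), t_eval=times,
                              check_invariants=prolif.model_id.value != "exponential")
        clean = np.clip(traj.sample_N(times), 0.0, 100.0)
        for rep in range(replicates):
            noisy = noise.apply(clean, rng)
            for t, v in zip(times, noisy):
                records.append((t, "Control", rep, v, seeding))
    df = pd.DataFrame(records, columns=OBS_COLUMNS)
    prov = _provenance("control_growth", noise, seed,
                       {"prolif": _clean(prolif.__dict__),
                        "seedings": list(seedings), "replicates": replicates})
    return ObservationSet(df, prov)


def generate_regimen_data(params_true: PSM1DParams,
                          regimens: Mapping[str, RegimenSchedule] | None = None,
                          times: Sequence[float] | None = None,
                          noise: NoiseModel = NoiseModel(),
                          seed: int = 0, replicates: int = 3,
                          N0: float = 10.0,
                          observables: Sequence[str] = ("S", "T")
                          ) -> ObservationSet:
    """Three-regimen (Repeated / Resting / Sustained) one-drug datasets.

    Densities are sampled on the 24-h grid at left limits (the dish is
    measured just before wash + treat).  By default observations are
    compartment-resolved (S and T rows), emulating treatment experiments
    in which the density drop caused by a drug input splits the measured
    density into its killed (sensitive) and surviving (tolerant) parts;
    pass ``observables=("N",)`` for total-density-only data.
    """
    if regimens is None:
        regimens = three_regimens(params_true.drug.drug_id,
                                  params_true.drug.D_input)
    rng = np.random.default_rng(seed)
    records = []
    for name, sched in regimens.items():
        obs_t = np.asarray(times, dtype=float) if times is not None \
            else sched.observation_times()
        traj = simulate_psm1d(params_true, sched,
                              y0=_scaled_initial_1d(params_true, N0))
        vals = traj.sample(obs_t, side="left")
        series = {}
        for obs_name in observables:
            if obs_name == "N":
                series["N"] = traj.sample_N(obs_t, side="left")
            else:
                series[obs_name] = vals[:, traj.columns.index(obs_name)]
        for rep in range(replicates):
            for obs_name, clean in series.items():
                noisy = noise.apply(np.clip(clean, 0.0, 100.0), rng)
                for t, v in zip(obs_t, noisy):
                    records.append((t, name, rep, v, N0, obs_name))
        del traj
    df = pd.DataFrame(records, columns=OBS_COLUMNS + ["compartment"])
    prov = _provenance("regimen_psm1d", noise, seed,
                       {"topology_index": params_true.topology.index,
                        "topology": params_true.topology.label(),
                        "params": json.loads(params_to_json(params_true)),
                        "N0": N0, "replicates": replicates,
                        "observables": list(observables)})
    return ObservationSet(df, prov)


def _scaled_initial_1d(params: PSM1DParams, N0: float) -> np.ndarray:
    from .model import initial_state_psm1d
    return initial_state_psm1d(params, N0=N0)


def generate_psm2d_data(params_true: PSM2DParams,
                        schedules: Mapping[str, RegimenSchedule] | None = None,
                        times: Sequence[float] | None = None,
                        noise: NoiseModel = NoiseModel(),
                        seed: int = 0, replicates: int = 3,
                        N0: float = 10.0) -> ObservationSet:
    """Two-drug datasets: repeated drug A versus the alternated A/N
    sequence (A at day 0, N at day 1, A at day 2, N at day 3)."""
    if schedules is None:
        dose_A = params_true.drug_A.drug.D_input
        dose_N = params_true.drug_N.drug.D_input
        schedules = {
            "Repeated": repeated(DrugId.A, dose_A, n_inputs=4, horizon=96.0),
            "Alternated": alternated(dose_A, dose_N, n_inputs=4, horizon=96.0),
        }
    from .psm2d import initial_state_psm2d
    rng = np.random.default_rng(seed)
    records = []
    for name, sched in schedules.items():
        obs_t = np.asarray(times, dtype=float) if times is not None \
            else sched.observation_times()
        traj = simulate_psm2d(params_true, sched,
                              y0=initial_state_psm2d(params_true, N0=N0))
        clean = np.clip(traj.sample_N(obs_t, side="left"), 0.0, 100.0)
        for rep in range(replicates):
            noisy = noise.apply(clean, rng)
            for t, v in zip(obs_t, noisy):
                records.append((t, name, rep, v, N0, "N"))
    df = pd.DataFrame(records, columns=OBS_COLUMNS + ["compartment"])
    prov = _provenance("regimen_psm2d", noise, seed,
                       {"params": json.loads(params_to_json(params_true)),
                        "N0": N0, "replicates": replicates})
    return ObservationSet(df, prov)
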