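"""Treatment schedules: timed drug inputs with wash semantics.

A schedule is an ordered list of :class:`DoseEvent`.  At a wash event all
drug concentrations in the dish are set to zero (the medium is replaced)
before the event's own dose, if any, is applied; without a wash the dose
adds to whatever drug is still present.  Any event with a positive dose
is a cytotoxic impulse for its drug's kill set.

The standard regimens from the experimental design are provided as
builders:

- ``repeated``:  wash + fresh drug every 24 h;
- ``resting``:   drug, then a 24 h drug holiday (wash only), then drug;
- ``sustained``: a single dose never washed out;
- ``alternated``: drugs A and N administered on alternating days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import DrugId

__all__ = ["DoseEvent", "RegimenSchedule", "repeated", "resting", "sustained",
           "alternated", "no_drug", "schedule_to_csv", "schedule_from_csv"]


@dataclass(frozen=True)
class DoseEvent:
    drug_id: DrugId
    time_h: float
    dose: float
    wash: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_id", DrugId(self.drug_id))
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.time_h < 0:
            raise ValueError(f"event time must be >= 0, got {self.time_h}")


@dataclass(frozen=True)
class RegimenSchedule:
    """Ordered drug-input events plus the simulation horizon (hours)."""

    events: tuple[DoseEvent, ...] = ()
    horizon: float = 168.0
    observation_interval: float = 24.0
    name: str = ""

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time_h))
        times = [e.time_h for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if events and events[-1].time_h > self.horizon:
            raise ValueError("all event times must lie within [0, horizon]")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        object.__setattr__(self, "events", events)

    @property
    def event_times(self) -> np.ndarray:
        return np.array([e.time_h for e in self.events], dtype=float)

    def observation_times(self) -> np.ndarray:
        """The sampling grid (default every 24 h up to the horizon)."""
        return np.arange(0.0, self.horizon + 1e-9, self.observation_interval)

    def with_horizon(self, horizon: float) -> "RegimenSchedule":
        return replace(self, horizon=horizon)

    def last_input_time(self) -> float:
        dosed = [e.time_h for e in self.events if e.dose > 0]
        return max(dosed) if dosed else 0.0


def no_drug(horizon: float = 168.0) -> RegimenSchedule:
    """Control: no events at all."""
    return RegimenSchedule(events=(), horizon=horizon, name="Control")


def repeated(drug_id: DrugId = DrugId.A, dose: float = 20.0, n_inputs: int = 3,
             interval: float = 24.0, horizon: float = 168.0) -> RegimenSchedule:
    events = tuple(
        DoseEvent(drug_id, i * interval, dose, wash=True) for i in range(n_inputs)
    )
    return RegimenSchedule(events=events, horizon=horizon, name="Repeated")


def resting(drug_id: DrugId = DrugId.A, dose: float = 20.0,
            horizon: float = 168.0) -> RegimenSchedule:
    events = (
        DoseEvent(drug_id, 0.0, dose, wash=True),
        DoseEvent(drug_id, 24.0, 0.0, wash=True),   # drug removed, no new input
        DoseEvent(drug_id, 48.0, dose, wash=True),
    )
    return RegimenSchedule(events=events, horizon=horizon, name="Resting")


def sustained(drug_id: DrugId = DrugId.A, dose: float = 20.0,
              horizon: float = 168.0) -> RegimenSchedule:
    events = (DoseEvent(drug_id, 0.0, dose, wash=True),)
    return RegimenSchedule(events=events, horizon=horizon, name="Sustained")


def alternated(dose_A: float = 20.0, dose_N: float = 10.0, n_inputs: int = 4,
               interval: float = 24.0, horizon: float | None = None) -> RegimenSchedule:
    """Drug A on even days, drug N on odd days (A at t=0, N at 24 h, ...)."""
    events = tuple(
        DoseEvent(DrugId.A if i % 2 == 0 else DrugId.N, i * interval,
                  dose_A if i % 2 == 0 else dose_N, wash=True)
        for i in range(n_inputs)
    )
    if horizon is None:
        horizon = n_inputs * interval
    return RegimenSchedule(events=events, horizon=horizon, name="Alternated")


def three_regimens(drug_id: DrugId = DrugId.A, dose: float = 20.0,
                   horizon: float = 168.0) -> dict[str, RegimenSchedule]:
    """The three one-drug regimens used throughout calibration."""
    return {
        "Repeated": repeated(drug_id, dose, horizon=horizon),
        "Resting": resting(drug_id, dose, horizon=horizon),
        "Sustained": sustained(drug_id, dose, horizon=horizon),
    }


# ---------------------------------------------------------------------------
# CSV round trip.  Times may be given in hours (column ``time_h``) or days
# (column ``time_day``); days are converted on read.


def schedule_to_csv(schedule: RegimenSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [e.drug_id.value for e in schedule.events],
            "time_h": [e.time_h for e in schedule.events],
            "dose": [e.dose for e in schedule.events],
            "wash": [int(e.wash) for e in schedule.events],
        }
    )
    df.to_csv(path, index=False)


def schedule_from_csv(path, horizon: float = 168.0,
                      name: str = "") -> RegimenSchedule:
    df = pd.read_csv(path)
    if "time_h" in df.columns:
        times = df["time_h"].astype(float)
    elif "time_day" in df.columns:
        times = df["time_day"].astype(float) * 24.0
    else:
        raise ValueError("schedule CSV needs a 'time_h' or 'time_day' column")
    missing = {"drug_id", "dose"} - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
    wash = df["wash"].astype(bool) if "wash" in df.columns else [True] * len(df)
    events = tuple(
        DoseEvent(DrugId(str(d)), float(t), float(dose), bool(w))
        for d, t, dose, w in zip(df["drug_id"], times, df["dose"], wash)
    )
    return RegimenSchedule(events=events, horizon=max(horizon, float(times.max() if len(df) else 0.0)),
                           name=name)
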