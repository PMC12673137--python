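"""Piecewise-smooth trajectories with left/right limits at impulse times."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

_DENSITY_SETS = (("S", "T"), ("S_A", "S_N", "T"))


@dataclass
class Trajectory:
    """Sampled solution of an impulsive ODE system.

    ``times`` is non-decreasing and contains *two* rows at every impulse
    time: the left limit first, the right limit second.  Memory variables
    and the tolerant compartment are continuous across impulses; the
    drug-sensitive compartments and the drug concentrations jump.
    """

    times: np.ndarray
    states: np.ndarray                # (len(times), len(columns))
    columns: tuple[str, ...]
    impulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    impulse_left: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    impulse_right: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.columns)):
            raise ValueError("states shape does not match times/columns")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    # -- access -----------------------------------------------------------

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def density_columns(self) -> tuple[str, ...]:
        for cand in _DENSITY_SETS:
            if set(cand) <= set(self.columns):
                return cand
        raise ValueError("trajectory has no recognizable density columns")

    @property
    def N(self) -> np.ndarray:
        """Total cell density S + T (or S_A + S_N + T) at every stored row."""
        idx = [self.columns.index(c) for c in self.density_columns]
        return self.states[:, idx].sum(axis=1)

    def sample(self, t, side: str = "left") -> np.ndarray:
        """Interpolate states at query times.

        At an impulse time the ``side`` argument selects the limit;
        observations taken at a dosing time use the left (pre-treatment)
        limit, matching a dish measured just before wash + treat.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, self.states.shape[1]))
        for i, tq in enumerate(t):
            if tq < self.times[0] - 1e-9 or tq > self.times[-1] + 1e-9:
                raise ValueError(f"query time {tq} outside trajectory span")
            if side == "left":
                j = int(np.searchsorted(self.times, tq, side="left"))
                j = min(j, self.times.size - 1)
                if abs(self.times[j] - tq) < 1e-12:
                    out[i] = self.states[j]
                    continue
            else:
                j = int(np.searchsorted(self.times, tq, side="right")) - 1
                if abs(self.times[j] - tq) < 1e-12:
                    out[i] = self.states[j]
                    continue
                j += 1
            j0 = max(j - 1, 0)
            t0, t1 = self.times[j0], self.times[j]
            w = 0.0 if t1 == t0 else (tq - t0) / (t1 - t0)
            out[i] = (1 - w) * self.states[j0] + w * self.states[j]
        return out

    def sample_N(self, t, side: str = "left") -> np.ndarray:
        idx = [self.columns.index(c) for c in self.density_columns]
        return self.sample(t, side=side)[:, idx].sum(axis=1)

    # -- export -----------------------------------------------------------

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time_h", self.times)
        df["N"] = self.N
        return df

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)
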