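"""File interfaces: observation CSVs, run configuration, provenance logs.

Observation files are long-format CSV with the header
``time_h, regimen, replicate, density_pct`` (``seeding_pct`` optional).
Validation errors name the offending rows.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import _clean
from .synthetic import ObservationSet

__all__ = ["read_timeseries", "write_timeseries", "RunConfig",
           "write_provenance"]

_REQUIRED = ["time_h", "regimen", "replicate", "density_pct"]


class TimeseriesFormatError(ValueError):
    """Raised for malformed observation files, naming the offending rows."""


def read_timeseries(path) -> ObservationSet:
    """Read and validate a long-format density time series.

    Raises :class:`TimeseriesFormatError` on missing columns, non-numeric
    or out-of-range densities, or an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TimeseriesFormatError(f"{path}: no records (empty file)") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TimeseriesFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TimeseriesFormatError(f"{path}: no records")
    dens = pd.to_numeric(df["density_pct"], errors="coerce")
    bad = df.index[~np.isfinite(dens)].tolist()
    if bad:
        raise TimeseriesFormatError(
            f"{path}: non-numeric density in rows {bad[:10]}")
    out_of_range = df.index[(dens < 0) | (dens > 100)].tolist()
    if out_of_range:
        raise TimeseriesFormatError(
            f"{path}: density outside [0, 100] in rows {out_of_range[:10]}")
    df["density_pct"] = dens
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise")
    if "seeding_pct" not in df.columns:
        df["seeding_pct"] = np.nan
    prov_path = path.with_suffix(".provenance.json")
    prov = {}
    if prov_path.exists():
        with open(prov_path) as fh:
            prov = json.load(fh)
    return ObservationSet(df, prov)


def write_timeseries(obs: ObservationSet, path, with_provenance: bool = True
                     ) -> None:
    path = Path(path)
    obs.to_csv(path, provenance_path=path.with_suffix(".provenance.json")
               if with_provenance and obs.provenance else None)


_RANGES = {
    "rtol": (1e-13, 1e-2),
    "atol": (1e-15, 1e-2),
    "n_starts": (1, 1000),
    "extinction_threshold": (0.0, 100.0),
    "occupation_threshold": (0.0, 100.0),
    "equilibrium_tol": (0.0, 50.0),
    "noise_sigma": (0.0, 50.0),
}


@dataclass
class RunConfig:
    """Validated settings shared by the pipeline entry points."""

    data_path: str | None = None
    output_dir: str = "."
    proliferation_form: str = "hill"
    topology_indices: tuple[int, ...] = tuple(range(1, 9))
    rtol: float = 1e-8
    atol: float = 1e-10
    n_starts: int = 10
    seed: int = 0
    weights: dict = field(default_factory=dict)
    extinction_threshold: float = 0.1
    occupation_threshold: float = 99.5
    equilibrium_tol: float = 1.0
    noise_sigma: float = 1.0

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if any(i not in range(1, 9) for i in self.topology_indices):
            raise ValueError("topology indices must be in 1..8")
        if self.data_path is not None and not Path(self.data_path).exists():
            raise ValueError(f"data path {self.data_path} does not exist")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=2)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(_clean(asdict(self)), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_provenance(path, config: RunConfig | None = None,
                     seed: int | None = None, **extra) -> dict:
    """Write a provenance sidecar (versions, config hash, seed) as JSON."""
    from . import __version__
    import scipy

    record = {
        "phenoswitch": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_digest": config.digest() if config else None,
        **_clean(extra),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return record
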