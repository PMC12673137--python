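"""Domain types for the phenotypic switch models.

Densities are expressed in percent of dish area occupied, time in hours,
drug amounts in the dose units of the corresponding treatment (for the
TRAIL-like drug these are ng/ml-equivalents).  All types validate their
invariants on construction and raise :class:`ValueError` on violation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
import numpy as np

__all__ = [
    "ProliferationModel",
    "ProliferationParams",
    "DrugId",
    "DrugParams",
    "SwitchRates",
    "MemoryParams",
    "MemoryBank",
    "Topology",
    "TOPOLOGY_TABLE",
    "all_topologies",
    "PSM1DParams",
    "CouplingParams",
    "PSM2DParams",
    "params_to_json",
    "params_from_json",
]


class ProliferationModel(str, Enum):
    """Candidate per-capita growth laws for the global population."""

    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    HILL = "hill"


# integer codes shared with the compiled kernels
_PROLIF_CODE = {
    ProliferationModel.EXPONENTIAL: 0,
    ProliferationModel.LOGISTIC: 1,
    ProliferationModel.GOMPERTZ: 2,
    ProliferationModel.HILL: 3,
}

#: floor (in % area) used to cap the Gompertz rate near N = 0, where
#: ln(N_max / N) diverges.
GOMPERTZ_FLOOR = 1e-3


@dataclass(frozen=True)
class ProliferationParams:
    """Parameters of the population growth law.

    Parameters
    ----------
    model_id : ProliferationModel
        Which growth law to use.  The Hill law ``beta * (1 - (N/N_max)**n)``
        is the default choice for confluent dish growth; a rational variant
        ``beta / (1 + (N/N_max)**n)`` is available via ``hill_rational``.
    beta : float
        Per-capita growth rate at low density (1/h).
    n : float
        Shape exponent of the Hill law (dimensionless); ignored by the
        other laws.
    N_max : float
        Carrying capacity, fixed at 100 % of dish area by default.
    hill_rational : bool
        Select the rational Hill form instead of the saturating polynomial
        form.
    """

    model_id: ProliferationModel = ProliferationModel.HILL
    beta: float = 0.04
    n: float = 2.0
    N_max: float = 100.0
    hill_rational: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ProliferationModel(self.model_id))
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if self.N_max <= 0:
            raise ValueError(f"N_max must be > 0, got {self.N_max}")

    @property
    def code(self) -> int:
        return _PROLIF_CODE[self.model_id]


class DrugId(str, Enum):
    """A: pro-apoptotic (TRAIL-like); N: pro-necroptotic (TBQ-like)."""

    A = "A"
    N = "N"


@dataclass(frozen=True)
class DrugParams:
    """Pharmacokinetic / impulsive-kill parameters of one drug.

    The drug concentration decays piecewise linearly at rate ``k_d``
    between administrations and is reset to the administered dose at each
    wash + treat event.  At each administration the drug-sensitive
    compartment is multiplied by the surviving fraction ``kappa``
    (0 by default: complete impulsive kill of sensitive cells).
    ``D_50`` is the half-saturation constant of the drug-stress input to
    the memory variables (Emax-type saturation).
    """

    drug_id: DrugId = DrugId.A
    D_input: float = 20.0
    k_d: float = 0.8
    D_50: float = 20.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_id", DrugId(self.drug_id))
        if self.D_input <= 0:
            raise ValueError(f"D_input must be > 0, got {self.D_input}")
        if self.k_d < 0:
            raise ValueError(f"k_d must be >= 0, got {self.k_d}")
        if self.D_50 <= 0:
            raise ValueError(f"D_50 must be > 0, got {self.D_50}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")


@dataclass(frozen=True)
class SwitchRates:
    """Baseline (drug-free) phenotypic switching rates, 1/h.

    ``alpha_ST0`` moves sensitive cells toward tolerance, ``alpha_TS0``
    the reverse.  The two rates are independent: switching is asymmetric.
    """

    alpha_ST0: float = 0.01
    alpha_TS0: float = 0.04

    def __post_init__(self) -> None:
        if self.alpha_ST0 < 0 or self.alpha_TS0 < 0:
            raise ValueError("switching rates must be >= 0")


@dataclass(frozen=True)
class MemoryParams:
    """Charge / discharge rates of one drug-memory variable.

    ``mu`` (1/h) is the sensitivity of the memory to drug stress,
    ``lambda_`` (1/h) the reset speed at which the memory is forgotten
    once the drug is gone.  At constant drug level D the memory relaxes to
    ``(mu / lambda_) * D / (D + D_50)``.
    """

    mu: float = 0.05
    lambda_: float = 0.02

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.lambda_ <= 0:
            raise ValueError(f"lambda_ must be > 0, got {self.lambda_}")


@dataclass(frozen=True)
class MemoryBank:
    """One memory variable per drug-modulated rate (ST, TS, beta)."""

    ST: MemoryParams = field(default_factory=MemoryParams)
    TS: MemoryParams = field(default_factory=MemoryParams)
    beta: MemoryParams = field(default_factory=MemoryParams)


@dataclass(frozen=True)
class Topology:
    """One of the eight drug-effect hypotheses.

    Three binary flags select whether the drug (through its memory
    variables) activates S->T switching, inhibits T->S switching and/or
    inhibits proliferation.  Every flag combination has a canonical index
    1..8 (see :data:`TOPOLOGY_TABLE`); the two variants best supported by
    calibration against the apoptotic and necroptotic treatments sit at
    indices 3 (+,-,-) and 2 (+,=,-).
    """

    activate_ST: bool = False
    inhibit_TS: bool = False
    inhibit_beta: bool = False

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.activate_ST, self.inhibit_TS, self.inhibit_beta)

    @property
    def index(self) -> int:
        return _FLAGS_TO_INDEX[self.flags]

    @classmethod
    def from_index(cls, index: int) -> "Topology":
        try:
            flags = TOPOLOGY_TABLE[index]
        except KeyError:
            raise ValueError(f"topology index must be 1..8, got {index}") from None
        return cls(*flags)

    def label(self) -> str:
        """Signed label, e.g. ``(+,-,=)``: + activation, - inhibition, = no effect."""
        return "(%s,%s,%s)" % (
            "+" if self.activate_ST else "=",
            "-" if self.inhibit_TS else "=",
            "-" if self.inhibit_beta else "=",
        )

    @property
    def is_null(self) -> bool:
        return not any(self.flags)


#: Canonical enumeration of the eight topologies.  Flags are
#: (activate_ST, inhibit_TS, inhibit_beta).
TOPOLOGY_TABLE: dict[int, tuple[bool, bool, bool]] = {
    1: (False, False, False),  # (=,=,=) null: drug kills but leaves rates alone
    2: (True, False, True),    # (+,=,-)
    3: (True, True, True),     # (+,-,-)
    4: (True, True, False),    # (+,-,=)
    5: (True, False, False),   # (+,=,=)
    6: (False, True, True),    # (=,-,-)
    7: (False, True, False),   # (=,-,=)
    8: (False, False, True),   # (=,=,-)
}
_FLAGS_TO_INDEX = {v: k for k, v in TOPOLOGY_TABLE.items()}


def all_topologies() -> list[Topology]:
    """The eight topologies in canonical index order."""
    return [Topology.from_index(i) for i in sorted(TOPOLOGY_TABLE)]


@dataclass(frozen=True)
class PSM1DParams:
    """Full parameter bundle of the one-drug phenotypic switch model."""

    prolif: ProliferationParams = field(default_factory=ProliferationParams)
    drug: DrugParams = field(default_factory=DrugParams)
    switch: SwitchRates = field(default_factory=SwitchRates)
    memory: MemoryBank = field(default_factory=MemoryBank)
    topology: Topology = field(default_factory=lambda: Topology.from_index(3))


@dataclass(frozen=True)
class CouplingParams:
    """Drug-A-driven sensitization of tolerant cells to drug N.

    The pro-apoptotic drug charges a dedicated memory variable (rate
    ``mu_TSN``, reset ``lambda_TSN``) that multiplicatively activates the
    T -> S_N switching rate in the two-drug model.
    """

    mu_TSN: float = 2.5
    lambda_TSN: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_TSN < 0:
            raise ValueError(f"mu_TSN must be >= 0, got {self.mu_TSN}")
        if self.lambda_TSN <= 0:
            raise ValueError(f"lambda_TSN must be > 0, got {self.lambda_TSN}")


@dataclass(frozen=True)
class PSM2DParams:
    """Two-drug model: two one-drug parameter bundles plus the coupling.

    The one-drug parameter values are reused unchanged; the shared
    proliferation law is taken from ``drug_A.prolif``.
    """

    drug_A: PSM1DParams = field(default_factory=PSM1DParams)
    drug_N: PSM1DParams = field(default_factory=PSM1DParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)

    def __post_init__(self) -> None:
        if self.drug_A.drug.drug_id == self.drug_N.drug.drug_id:
            raise ValueError("the two drugs must carry distinct drug ids")


# ---------------------------------------------------------------------------
# JSON (de)serialization of parameter bundles


def _clean(obj):
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def params_to_json(params: PSM1DParams | PSM2DParams, path=None) -> str:
    """Serialize a parameter bundle to JSON (returned, and written if *path*)."""
    kind = "psm2d" if isinstance(params, PSM2DParams) else "psm1d"
    payload = {"kind": kind, **_clean(asdict(params))}
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def _psm1d_from_dict(d: dict) -> PSM1DParams:
    topo = d.get("topology", {})
    return PSM1DParams(
        prolif=ProliferationParams(**d.get("prolif", {})),
        drug=DrugParams(**d.get("drug", {})),
        switch=SwitchRates(**d.get("switch", {})),
        memory=MemoryBank(**{k: MemoryParams(**v) for k, v in d.get("memory", {}).items()}),
        topology=Topology(**topo) if topo else Topology.from_index(3),
    )


def params_from_json(source) -> PSM1DParams | PSM2DParams:
    """Load a parameter bundle from a JSON string or file path."""
    text = source
    if not str(source).lstrip().startswith("{"):
        with open(source) as fh:
            text = fh.read()
    d = json.loads(text)
    kind = d.pop("kind", "psm1d")
    if kind == "psm2d":
        return PSM2DParams(
            drug_A=_psm1d_from_dict(d["drug_A"]),
            drug_N=_psm1d_from_dict(d["drug_N"]),
            coupling=CouplingParams(**d.get("coupling", {})),
        )
    if kind != "psm1d":
        raise ValueError(f"unknown parameter bundle kind {kind!r}")
    return _psm1d_from_dict(d)
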