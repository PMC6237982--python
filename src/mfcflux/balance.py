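"""Per-cycle electron-flux partition: anode respiration vs. denitrification vs. losses.

One fed-batch cycle of a two-chamber MFC liberates a total charge ``c_t``
from substrate oxidation (measured as the COD drop).  That charge splits
three ways:

* ``c_an`` — anode respiration, the charge actually collected by the
  circuit, obtained by integrating I(t) = V(t)/R_ext over the cycle;
* ``c_de`` — anodic denitrification, 5 e- per mole of nitrate-N lost
  (assumed reduced fully to N2);
* ``c_ot`` — the residual: biomass synthesis plus overpotential losses,
  defined as c_t - c_an - c_de and never clamped (a negative residual is a
  measurement-inconsistency signal, reported via ConservationWarning).

From the partition follow the coulombic efficiency CE = c_an/c_t and the
corrected coulombic efficiency CCE = c_an/(c_t - c_de), which removes the
denitrification draw from the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import (
    ConservationWarning,
    DataQualityWarning,
    DomainError,
    InsufficientDataError,
)
from .stoichiometry import (
    DEFAULT_CONSTANTS,
    StoichiometryConstants,
    cod_equivalent_of_charge,
    electrons_from_cod,
    electrons_from_nitrate,
)

__all__ = [
    "ReactorSpec",
    "BatchCycleRecord",
    "ElectronBalance",
    "integrate_current",
    "total_electrons",
    "partition",
    "electron_fractions",
    "net_cod_n_ratio",
]

#: Voltage below which the anolyte is considered spent and the cycle over.
CYCLE_END_VOLTAGE_V = 0.02


@dataclass(frozen=True)
class ReactorSpec:
    """Reactor geometry/circuit constants of the two-chamber MFC.

    Defaults: 15 mL chambers, 1 kOhm external resistor, 7 cm2 air cathode.
    """

    anolyte_volume_l: float = 0.015
    external_resistance_ohm: float = 1000.0
    cathode_area_m2: float = 7e-4

    def __post_init__(self) -> None:
        if self.anolyte_volume_l <= 0 or self.external_resistance_ohm <= 0 or self.cathode_area_m2 <= 0:
            raise DomainError("reactor constants must be strictly positive")


@dataclass
class BatchCycleRecord:
    """Multichannel time series of one fed-batch cycle; the unit of analysis.

    Concentration channels use NaN for "not measured at this sample"; COD
    and nitrate-N must be present at least at the first and last sample.
    """

    time_h: np.ndarray
    voltage_v: np.ndarray
    cod_mg_l: np.ndarray
    no3n_mg_l: np.ndarray
    no2n_mg_l: np.ndarray | None = None
    nh4n_mg_l: np.ndarray | None = None
    reactor: ReactorSpec = field(default_factory=ReactorSpec)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.voltage_v = np.asarray(self.voltage_v, dtype=float)
        self.cod_mg_l = np.asarray(self.cod_mg_l, dtype=float)
        self.no3n_mg_l = np.asarray(self.no3n_mg_l, dtype=float)
        for name in ("no2n_mg_l", "nh4n_mg_l"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        n = self.time_h.size
        for name in ("voltage_v", "cod_mg_l", "no3n_mg_l"):
            if getattr(self, name).size != n:
                raise DomainError(f"{name} length does not match time_h")
        if n >= 2 and not np.all(np.diff(self.time_h) > 0):
            bad = int(np.flatnonzero(np.diff(self.time_h) <= 0)[0]) + 1
            raise DomainError(f"time_h must be strictly increasing (violated at row {bad})")
        if np.any(self.voltage_v < 0):
            raise DomainError("voltages must be >= 0")
        for name in ("cod_mg_l", "no3n_mg_l", "no2n_mg_l", "nh4n_mg_l"):
            val = getattr(self, name)
            if val is not None and np.any(val[~np.isnan(val)] < 0):
                raise DomainError(f"{name} must be >= 0 where measured")
        for name in ("cod_mg_l", "no3n_mg_l"):
            val = getattr(self, name)
            if n and (math.isnan(val[0]) or math.isnan(val[-1])):
                raise DomainError(f"{name} must be measured at the first and last sample")

    @property
    def n_samples(self) -> int:
        return int(self.time_h.size)

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def delta(self, channel: str) -> float:
        """Endpoint drop (first minus last measured value) of a channel, mg/L."""
        series = getattr(self, channel)
        return float(series[0] - series[-1])


@dataclass(frozen=True)
class ElectronBalance:
    """The three-way electron partition of one cycle, in Coulombs.

    ``c_ot`` is the exact residual ``c_t - c_an - c_de`` by construction.
    CE/CCE are NaN where their denominators vanish.
    """

    c_t: float
    c_an: float
    c_de: float

    @property
    def c_ot(self) -> float:
        return self.c_t - self.c_an - self.c_de

    @property
    def ce_pct(self) -> float:
        if self.c_t == 0:
            if self.c_an > 0:
                raise DomainError("CE undefined: zero total electrons with nonzero anode charge")
            return math.nan
        return 100.0 * self.c_an / self.c_t

    @property
    def cce_pct(self) -> float:
        denom = self.c_t - self.c_de
        if denom == 0:
            return math.nan
        return 100.0 * self.c_an / denom

    @property
    def fractions(self) -> dict[str, float]:
        """Fractions of c_t: anode respiration / anodic denitrification / others."""
        return electron_fractions(self)


def integrate_current(cycle: BatchCycleRecord) -> float:
    """Charge collected by the circuit (C): trapezoidal integral of V(t)/R.

    Time is converted from hours to seconds; the trapezoidal rule is exact
    for the piecewise-linear voltage traces a 5-min logger produces.
    """
    if cycle.n_samples < 2:
        raise InsufficientDataError("need at least 2 voltage samples to integrate current")
    current_a = cycle.voltage_v / cycle.reactor.external_resistance_ohm
    return float(np.trapezoid(current_a, cycle.time_h * 3600.0))


def total_electrons(
    cycle: BatchCycleRecord,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
    cod_increase_tolerance_mg_l: float = 5.0,
) -> float:
    """Total charge liberated by substrate oxidation (C), from the COD drop.

    Uses the endpoint COD difference times the anolyte volume.  An apparent
    COD increase beyond ``cod_increase_tolerance_mg_l`` raises a
    DataQualityWarning; any increase is treated as zero consumption.
    """
    delta_mg_l = cycle.delta("cod_mg_l")
    if delta_mg_l < -cod_increase_tolerance_mg_l:
        warnings.warn(
            f"COD increased by {-delta_mg_l:.1f} mg/L over the cycle; treating consumption as zero",
            DataQualityWarning,
            stacklevel=2,
        )
    delta_mg = max(delta_mg_l, 0.0) * cycle.reactor.anolyte_volume_l
    return electrons_from_cod(delta_mg, constants)


def partition(
    cycle: BatchCycleRecord,
    include_nitrite_correction: bool = False,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> ElectronBalance:
    """Partition one cycle's electrons into (c_t, c_an, c_de, c_ot).

    A negative residual ``c_ot`` is reported as-is with a
    ConservationWarning; residual ammonium-N at cycle end triggers a
    DataQualityWarning because dissimilatory nitrate reduction to ammonium
    would consume 8 e- per mole and is not accounted for here.
    """
    c_t = total_electrons(cycle, constants)
    c_an = integrate_current(cycle)
    delta_no3_mg = max(cycle.delta("no3n_mg_l"), 0.0) * cycle.reactor.anolyte_volume_l
    residual_no2_mg = 0.0
    if cycle.no2n_mg_l is not None and not math.isnan(cycle.no2n_mg_l[-1]):
        residual_no2_mg = float(cycle.no2n_mg_l[-1]) * cycle.reactor.anolyte_volume_l
    c_de = electrons_from_nitrate(
        delta_no3_mg,
        residual_no2n_mg=min(residual_no2_mg, delta_no3_mg) if include_nitrite_correction else 0.0,
        include_nitrite_correction=include_nitrite_correction,
        constants=constants,
    )
    bal = ElectronBalance(c_t=c_t, c_an=c_an, c_de=c_de)
    if c_t == 0 and c_an > 0:
        raise DomainError("CE undefined: COD shows no consumption but current flowed")
    if bal.c_ot < 0:
        warnings.warn(
            f"electron balance does not close: residual c_ot = {bal.c_ot:.2f} C < 0",
            ConservationWarning,
            stacklevel=2,
        )
    if cycle.nh4n_mg_l is not None and not math.isnan(cycle.nh4n_mg_l[-1]) and cycle.nh4n_mg_l[-1] > 0.1:
        warnings.warn(
            f"ammonium-N {cycle.nh4n_mg_l[-1]:.2f} mg/L at cycle end; dissimilatory "
            "reduction to ammonium (8 e-/mol) is not included in c_de",
            DataQualityWarning,
            stacklevel=2,
        )
    return bal


def electron_fractions(balance: ElectronBalance) -> dict[str, float]:
    """Fractions of total charge, summing to 1 exactly when c_t > 0."""
    if balance.c_t <= 0:
        raise DomainError("electron fractions undefined for c_t <= 0")
    f_an = balance.c_an / balance.c_t
    f_de = balance.c_de / balance.c_t
    return {
        "anode_respiration": f_an,
        "anodic_denitrification": f_de,
        "others": 1.0 - f_an - f_de,
    }


def net_cod_n_ratio(
    cycle: BatchCycleRecord,
    mode: Literal["residual", "dissimilatory"] = "residual",
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Net COD consumed per g of nitrate-N removed (g COD / g N).

    ``"residual"`` charges denitrification with everything the circuit did
    not collect (c_t - c_an), i.e. denitrification plus biomass/losses;
    ``"dissimilatory"`` charges only the stoichiometric c_de, which is the
    constant 5 e-/mol N == 2.86 g COD per g N regardless of the data.
    """
    if mode not in ("residual", "dissimilatory"):
        raise DomainError(f"unknown net COD/N mode {mode!r}")
    n_removed_mg = cycle.delta("no3n_mg_l") * cycle.reactor.anolyte_volume_l
    if n_removed_mg <= 0:
        raise DomainError("net COD/N undefined: no nitrate-N removed")
    bal = partition(cycle, constants=constants)
    charge = (bal.c_t - bal.c_an) if mode == "residual" else bal.c_de
    return cod_equivalent_of_charge(charge, constants) / n_removed_mg
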