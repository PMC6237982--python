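"""Synthetic batch cycles, polarization sweeps, and voltammograms.

The batch-cycle generator emulates the regime the analysis modules assume:
a fed-batch two-chamber MFC where anode respiration and denitrification
draw concurrently on one acetate (COD) pool — donor limitation, not
inhibition.  Mechanics:

* nitrate-N declines first-order with rate ``k_no3_h`` while the donor
  lasts, then freezes;
* cell voltage holds a plateau (``plateau_voltage_v`` across the external
  resistor) while COD remains, then decays exponentially to below the
  20 mV cycle-end threshold;
* a fixed fraction ``others_fraction`` of the liberated electrons goes to
  biomass synthesis and losses;
* the COD trajectory is constructed so that, before noise, the liberated
  electrons equal c_an + c_de + c_ot exactly — the generator returns this
  ground-truth partition alongside the record.

Measurement noise is multiplicative log-normal (mean 1, coefficient of
variation ``noise_cv``) with independent draws per channel and sample; all
output is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .balance import BatchCycleRecord, CYCLE_END_VOLTAGE_V, ElectronBalance, ReactorSpec
from .electrochem import PolarizationCurve, Voltammogram
from .exceptions import DomainError, InfeasibleConfigError, ParameterError
from .stoichiometry import (
    DEFAULT_CONSTANTS,
    StoichiometryConstants,
    cod_equivalent_of_charge,
    electrons_from_cod,
    electrons_from_nitrate,
)

__all__ = [
    "SimulationConfig",
    "CVPeak",
    "DEFAULT_RESISTANCE_SWEEP",
    "simulate_batch_cycle",
    "simulate_polarization",
    "simulate_cv",
]

#: External-resistance sweep spanning the conventional 100-5000 Ohm range.
DEFAULT_RESISTANCE_SWEEP: tuple[float, ...] = (100, 150, 200, 300, 500, 1000, 2000, 5000)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic batch cycle.

    Defaults mirror the reference reactor: 780.5 mg/L COD (1 g/L sodium
    acetate), 15 mL anolyte, 1 kOhm load, 7 cm2 cathode, ~0.45 V plateau,
    5-min logging, 2% multiplicative measurement noise.  ``k_no3_h`` of
    0.29/h reproduces ~83% nitrate removal within 6 h.  The default
    nitrate level (50 mg/L N) is the mid-range condition where corrected
    coulombic efficiency peaks.
    """

    initial_cod_mg_l: float = 780.5
    initial_no3n_mg_l: float = 50.0
    k_no3_h: float = 0.29
    plateau_voltage_v: float = 0.45
    external_resistance_ohm: float = 1000.0
    anolyte_volume_l: float = 0.015
    cathode_area_m2: float = 7e-4
    others_fraction: float = 0.10
    sample_interval_min: float = 5.0
    noise_cv: float = 0.02
    decay_tau_h: float = 0.5
    end_voltage_v: float = CYCLE_END_VOLTAGE_V

    def __post_init__(self) -> None:
        if not 0.0 <= self.others_fraction < 1.0:
            raise DomainError("others_fraction must lie in [0, 1)")
        for name in (
            "initial_cod_mg_l",
            "initial_no3n_mg_l",
            "k_no3_h",
            "noise_cv",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in (
            "plateau_voltage_v",
            "external_resistance_ohm",
            "anolyte_volume_l",
            "cathode_area_m2",
            "sample_interval_min",
            "decay_tau_h",
            "end_voltage_v",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.end_voltage_v >= self.plateau_voltage_v:
            raise DomainError("end_voltage_v must be below plateau_voltage_v")

    def replace(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)

    @property
    def reactor(self) -> ReactorSpec:
        return ReactorSpec(
            anolyte_volume_l=self.anolyte_volume_l,
            external_resistance_ohm=self.external_resistance_ohm,
            cathode_area_m2=self.cathode_area_m2,
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_batch_cycle(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> tuple[BatchCycleRecord, ElectronBalance]:
    """Generate one batch cycle plus its ground-truth electron partition.

    The plateau duration is solved from the electron budget: plateau charge
    + (analytic) decay-tail charge + denitrification charge must equal
    (1 - others_fraction) of the COD-derived total.  Nitrate follows
    first-order decay until the donor is exhausted at plateau end, then
    holds.  Raises InfeasibleConfigError when the COD pool cannot sustain
    any plateau at all.
    """
    c_t = electrons_from_cod(config.initial_cod_mg_l * config.anolyte_volume_l, constants)
    if c_t <= 0:
        raise InfeasibleConfigError("no COD: the cycle cannot produce any current")
    plateau_i = config.plateau_voltage_v / config.external_resistance_ohm  # A
    tau_s = config.decay_tau_h * 3600.0
    q_decay = plateau_i * tau_s  # full exponential-tail charge, C
    n0_mg = config.initial_no3n_mg_l * config.anolyte_volume_l
    usable = (1.0 - config.others_fraction) * c_t

    def c_de_at(t_h: float) -> float:
        removed = n0_mg * (1.0 - math.exp(-config.k_no3_h * t_h)) if config.k_no3_h > 0 else 0.0
        return electrons_from_nitrate(removed, constants=constants)

    def budget(t_h: float) -> float:
        return plateau_i * 3600.0 * t_h + q_decay + c_de_at(t_h) - usable

    if budget(0.0) >= 0:
        raise InfeasibleConfigError(
            "COD pool exhausted before any plateau current could flow; "
            "increase initial_cod_mg_l or reduce the load"
        )
    t_upper = usable / (plateau_i * 3600.0) + 1.0
    t_plateau = brentq(budget, 0.0, t_upper, xtol=1e-10)

    c_de = c_de_at(t_plateau)
    c_ot = config.others_fraction * c_t
    c_an = c_t - c_de - c_ot  # == plateau + full decay tail by construction
    truth = ElectronBalance(c_t=c_t, c_an=c_an, c_de=c_de)

    # sampling grid: regular logging plus the exact plateau-end corner (so the
    # trapezoidal re-integration of the emitted trace is not biased there);
    # the decay is recorded well past the cycle-end threshold so the charge
    # left in the unrecorded tail is negligible against ground truth
    dt_h = config.sample_interval_min / 60.0
    cutoff_v = config.end_voltage_v / 20.0
    t_decay_h = config.decay_tau_h * math.log(config.plateau_voltage_v / cutoff_v)
    t_total = t_plateau + t_decay_h
    t = np.arange(0.0, t_total + dt_h, dt_h)
    if not np.any(np.isclose(t, t_plateau, atol=1e-12)):
        t = np.sort(np.append(t, t_plateau))
    voltage = np.where(
        t <= t_plateau,
        config.plateau_voltage_v,
        config.plateau_voltage_v * np.exp(-(t - t_plateau) / config.decay_tau_h),
    )
    below = np.flatnonzero(voltage < cutoff_v)
    if below.size:
        t, voltage = t[: below[0] + 1], voltage[: below[0] + 1]

    no3 = config.initial_no3n_mg_l * np.exp(-config.k_no3_h * np.minimum(t, t_plateau))
    # transient nitrite bump, capped under 1 mg/L, vanishing by cycle end
    if config.initial_no3n_mg_l > 0 and config.k_no3_h > 0:
        shape = np.exp(-config.k_no3_h * np.minimum(t, t_plateau)) - np.exp(
            -3.0 * config.k_no3_h * np.minimum(t, t_plateau)
        )
        peak = shape.max()
        no2 = 0.8 * shape / peak if peak > 0 else np.zeros_like(t)
    else:
        no2 = np.zeros_like(t)
    nh4 = np.zeros_like(t)

    # cumulative liberated charge -> COD trajectory (endpoint-consistent)
    q_an_cum = np.where(
        t <= t_plateau,
        plateau_i * 3600.0 * t,
        plateau_i * 3600.0 * t_plateau
        + plateau_i * tau_s * (1.0 - np.exp(-(t - t_plateau) / config.decay_tau_h)),
    )
    c_de_cum = np.array([c_de_at(min(tt, t_plateau)) for tt in t])
    consumed = np.minimum((q_an_cum + c_de_cum) / (1.0 - config.others_fraction), c_t)
    cod = config.initial_cod_mg_l - cod_equivalent_of_charge(consumed, constants) / config.anolyte_volume_l
    cod = np.maximum(cod, 0.0)

    rng = np.random.default_rng(seed)
    voltage_n = voltage * _lognormal_factors(rng, config.noise_cv, t.size)
    cod_n = cod * _lognormal_factors(rng, config.noise_cv, t.size)
    no3_n = no3 * _lognormal_factors(rng, config.noise_cv, t.size)
    no2_n = no2 * _lognormal_factors(rng, config.noise_cv, t.size)

    record = BatchCycleRecord(
        time_h=t,
        voltage_v=voltage_n,
        cod_mg_l=cod_n,
        no3n_mg_l=no3_n,
        no2n_mg_l=no2_n,
        nh4n_mg_l=nh4,
        reactor=config.reactor,
    )
    return record, truth


def simulate_polarization(
    ocv_v: float,
    r_int_ohm: float,
    area_m2: float = 7e-4,
    resistances: Sequence[float] = DEFAULT_RESISTANCE_SWEEP,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> PolarizationCurve:
    """Linear equivalent-circuit polarization sweep: V = OCV * R / (R + R_int)."""
    if ocv_v <= 0 or r_int_ohm <= 0:
        raise DomainError("ocv_v and r_int_ohm must be > 0")
    r = np.asarray(resistances, dtype=float)
    if np.any(r <= 0):
        raise DomainError("all external resistances must be > 0")
    v = ocv_v * r / (r + r_int_ohm)
    v = v * _lognormal_factors(np.random.default_rng(seed), noise_cv, r.size)
    return PolarizationCurve(resistance_ohm=r, voltage_v=v, cathode_area_m2=area_m2)


@dataclass(frozen=True)
class CVPeak:
    """One Gaussian redox wave: center (V), height (A), width sigma (V), direction."""

    center_v: float
    height_a: float
    width_v: float
    kind: str  # "anodic" | "cathodic"

    def __post_init__(self) -> None:
        if self.kind not in ("anodic", "cathodic"):
            raise ParameterError(f"peak kind must be 'anodic' or 'cathodic', got {self.kind!r}")
        if self.height_a <= 0 or self.width_v <= 0:
            raise ParameterError("peak height and width must be > 0")


def simulate_cv(
    peaks: Sequence[CVPeak] = (),
    baseline_capacitive_a: float = 2e-5,
    window: tuple[float, float] = (-0.6, 0.2),
    step_v: float = 0.001,
    scan_rate_v_s: float = 0.001,
    noise_a: float = 0.0,
    seed: int = 0,
) -> Voltammogram:
    """Synthetic voltammogram: Gaussian redox waves on a capacitive baseline.

    The anodic segment sweeps ``window`` upward with positive capacitive
    offset and positive Gaussian oxidation waves; the cathodic segment
    sweeps back down with the signs reversed.  Peak centers outside the
    window trigger a warning (they cannot be detected).
    """
    lo, hi = window
    if step_v <= 0:
        raise DomainError("step_v must be > 0")
    if hi <= lo:
        raise DomainError("window must satisfy lo < hi")
    pot_up = np.arange(lo, hi + step_v / 2, step_v)
    pot_down = pot_up[::-1]
    cur_up = np.full_like(pot_up, baseline_capacitive_a)
    cur_down = np.full_like(pot_down, -baseline_capacitive_a)
    for pk in peaks:
        if not lo <= pk.center_v <= hi:
            import warnings

            warnings.warn(
                f"peak center {pk.center_v} V lies outside the sweep window {window}",
                UserWarning,
                stacklevel=2,
            )
        g_up = pk.height_a * np.exp(-0.5 * ((pot_up - pk.center_v) / pk.width_v) ** 2)
        if pk.kind == "anodic":
            cur_up = cur_up + g_up
        else:
            cur_down = cur_down - g_up[::-1]
    if noise_a > 0:
        rng = np.random.default_rng(seed)
        cur_up = cur_up + rng.normal(0.0, noise_a, cur_up.size)
        cur_down = cur_down + rng.normal(0.0, noise_a, cur_down.size)
    potential = np.concatenate([pot_up, pot_down])
    current = np.concatenate([cur_up, cur_down])
    segment = np.array(["anodic"] * pot_up.size + ["cathodic"] * pot_down.size, dtype=object)
    return Voltammogram(
        potential_v=potential,
        current_a=current,
        scan_rate_v_s=scan_rate_v_s,
        segment=segment,
    )
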