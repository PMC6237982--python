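"""Polarization-curve and cyclic-voltammetry analysis.

Polarization: the MFC is loaded with a sweep of external resistances
(typically 100-5000 Ohm) and the steady voltage recorded at each.  Current
and power densities are normalized to the cathode area; the maximum power
density (MPD) is read off the measured points (no interpolation), and the
apparent internal resistance comes from the slope of the V-I line.  For a
linear cell V = OCV - R_int * I, maximum power transfer puts the MPD at
R_ext == R_int.

Cyclic voltammetry: a slow triangular potential sweep (default 1 mV/s over
-0.6..0.2 V vs. Ag/AgCl).  Redox couples appear as current peaks; weak or
overlapping waves are resolved by the first derivative dI/dE, where each
oxidation wave contributes one derivative maximum ("inflection point") even
when the peaks themselves merge.  Sign convention: anodic (oxidation)
current positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import (
    DomainError,
    InconsistentDataError,
    InsufficientDataError,
    ParameterError,
    StageWarning,
)

__all__ = [
    "PolarizationCurve",
    "PolarizationReport",
    "Voltammogram",
    "PeakReport",
    "CycleStages",
    "polarization_analysis",
    "cv_first_derivative",
    "detect_redox_peaks",
    "stage_batch_for_cv",
]

MIN_SEGMENT_SAMPLES = 50  # minimum sweep samples for derivative analysis


@dataclass
class PolarizationCurve:
    """(R_ext, V) points of a resistance sweep plus cathode area."""

    resistance_ohm: np.ndarray
    voltage_v: np.ndarray
    cathode_area_m2: float = 7e-4

    def __post_init__(self) -> None:
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        self.voltage_v = np.asarray(self.voltage_v, dtype=float)
        if self.resistance_ohm.size != self.voltage_v.size:
            raise DomainError("resistance and voltage arrays must have equal length")
        if np.any(self.resistance_ohm <= 0):
            raise DomainError("external resistances must be > 0")
        if np.any(self.voltage_v < 0):
            raise DomainError("voltages must be >= 0")
        if self.cathode_area_m2 <= 0:
            raise DomainError("cathode area must be > 0")

    @property
    def current_a(self) -> np.ndarray:
        return self.voltage_v / self.resistance_ohm

    @property
    def current_density_a_m2(self) -> np.ndarray:
        return self.current_a / self.cathode_area_m2

    @property
    def power_density_w_m2(self) -> np.ndarray:
        return self.voltage_v * self.current_a / self.cathode_area_m2


@dataclass(frozen=True)
class PolarizationReport:
    mpd_w_m2: float
    current_density_at_mpd_a_m2: float
    resistance_at_mpd_ohm: float
    internal_resistance_ohm: float  # NaN when too few points to regress
    open_circuit_voltage_v: float  # V-axis intercept of the V-I regression
    is_located_maximum: bool  # False when the sweep cannot bracket the MPD


@dataclass
class Voltammogram:
    """One CV sweep: potential vs. Ag/AgCl, current, and direction labels.

    ``segment`` labels each sample ``"anodic"`` (potential increasing) or
    ``"cathodic"``; if omitted it is inferred from the sign of the local
    potential change.
    """

    potential_v: np.ndarray
    current_a: np.ndarray
    scan_rate_v_s: float = 0.001
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.potential_v = np.asarray(self.potential_v, dtype=float)
        self.current_a = np.asarray(self.current_a, dtype=float)
        if self.potential_v.size != self.current_a.size:
            raise DomainError("potential and current arrays must have equal length")
        if self.scan_rate_v_s <= 0:
            raise DomainError("scan rate must be > 0")
        if self.segment is None:
            # forward differences: the turning sample belongs to the sweep it starts
            d = np.diff(self.potential_v)
            labels = np.where(np.concatenate([d, d[-1:]]) >= 0, "anodic", "cathodic")
            self.segment = labels.astype(object)
        else:
            self.segment = np.asarray(self.segment, dtype=object)
            if self.segment.size != self.potential_v.size:
                raise DomainError("segment labels must match the sweep length")

    def segment_indices(self, direction: str) -> np.ndarray:
        return np.flatnonzero(self.segment == direction)

    @property
    def window(self) -> tuple[float, float]:
        return float(self.potential_v.min()), float(self.potential_v.max())


@dataclass(frozen=True)
class PeakReport:
    """Detected redox features of one voltammogram."""

    oxidation_potentials_v: tuple[float, ...] = ()
    oxidation_heights_a: tuple[float, ...] = ()
    reduction_potentials_v: tuple[float, ...] = ()
    reduction_heights_a: tuple[float, ...] = ()
    anodic_inflections_v: tuple[float, ...] = ()
    cathodic_inflections_v: tuple[float, ...] = ()


@dataclass(frozen=True)
class CycleStages:
    """The five sampling stages of one batch cycle (times in h; NaN = undefined)."""

    rise_h: float
    maximum_h: float
    plateau_mid_h: float
    decline_h: float
    end_h: float
    flags: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.rise_h, self.maximum_h, self.plateau_mid_h, self.decline_h, self.end_h)


def polarization_analysis(curve: PolarizationCurve) -> PolarizationReport:
    """Locate the maximum power density and estimate the internal resistance.

    MPD is the largest measured power density (discrete sweep, no
    interpolation).  Internal resistance is the negated least-squares slope
    of V against I; the intercept estimates the open-circuit voltage.  With
    fewer than 3 distinct resistances the report is flagged as not a
    located maximum and the regression quantities are NaN.
    """
    r, v = curve.resistance_ohm, curve.voltage_v
    order = np.lexsort((v, r))
    rs, vs = r[order], v[order]
    dup = np.diff(rs) == 0
    if np.any(dup & (np.abs(np.diff(vs)) > 1e-9)):
        bad = rs[:-1][dup & (np.abs(np.diff(vs)) > 1e-9)][0]
        raise InconsistentDataError(f"conflicting voltages recorded at R = {bad:g} Ohm")
    if r.size == 0:
        raise InsufficientDataError("empty polarization curve")

    p = curve.power_density_w_m2
    i_dens = curve.current_density_a_m2
    imax = int(np.argmax(p))
    located = np.unique(r).size >= 3
    current = curve.current_a
    if located and np.ptp(current) > 0:
        slope, intercept = np.polyfit(current, v, 1)
        r_int, ocv = -float(slope), float(intercept)
    else:
        r_int = ocv = float("nan")
    return PolarizationReport(
        mpd_w_m2=float(p[imax]),
        current_density_at_mpd_a_m2=float(i_dens[imax]),
        resistance_at_mpd_ohm=float(r[imax]),
        internal_resistance_ohm=r_int,
        open_circuit_voltage_v=ocv,
        is_located_maximum=located,
    )


def _segment_arrays(v: Voltammogram, direction: str) -> tuple[np.ndarray, np.ndarray]:
    idx = v.segment_indices(direction)
    pot, cur = v.potential_v[idx], v.current_a[idx]
    if pot.size and not (np.all(np.diff(pot) > 0) or np.all(np.diff(pot) < 0)):
        raise DomainError(f"{direction} segment potential is not monotone")
    return pot, cur


def cv_first_derivative(
    v: Voltammogram,
    smooth_window: int = 11,
    polyorder: int = 2,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """dI/dE per sweep direction after Savitzky-Golay smoothing.

    Returns ``{direction: (potential, dI/dE)}`` for each non-empty segment.
    The current is smoothed with a moving polynomial (default order 2,
    window 11 samples — a 1 mV-step raw derivative is noise-dominated),
    then differentiated by centered finite differences with one-sided
    endpoints (``numpy.gradient``).
    """
    if smooth_window % 2 == 0 or smooth_window < polyorder + 2:
        raise ParameterError("smooth_window must be odd and exceed the polynomial order + 1")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for direction in ("anodic", "cathodic"):
        pot, cur = _segment_arrays(v, direction)
        if pot.size == 0:
            continue
        if pot.size < MIN_SEGMENT_SAMPLES:
            raise InsufficientDataError(
                f"{direction} segment has {pot.size} samples; need >= {MIN_SEGMENT_SAMPLES}"
            )
        if smooth_window >= pot.size:
            raise ParameterError(
                f"smooth_window {smooth_window} >= {direction} segment length {pot.size}"
            )
        smoothed = savgol_filter(cur, smooth_window, polyorder)
        out[direction] = (pot, np.gradient(smoothed, pot))
    return out


def detect_redox_peaks(
    v: Voltammogram,
    prominence_fraction: float = 0.05,
    smooth_window: int = 11,
) -> PeakReport:
    """Locate oxidation/reduction peaks and derivative inflection points.

    Peaks are local current maxima (anodic sweep) or minima (cathodic) with
    prominence at least ``prominence_fraction`` of that segment's current
    range, and always above a robust noise floor (5x the point-noise sigma
    estimated from first differences, so a featureless noisy baseline
    yields no detections while a constant current offset changes nothing).
    Inflection points are prominent extrema of the smoothed dI/dE: maxima
    on the anodic sweep, minima on the cathodic — one per redox wave, which
    resolves shoulders that never separate into distinct peaks.  An empty
    report is a valid outcome.
    """
    if not 0.0 <= prominence_fraction <= 1.0:
        raise ParameterError("prominence_fraction must lie in [0, 1]")
    deriv = cv_first_derivative(v, smooth_window=smooth_window)

    def noise_sigma(x: np.ndarray) -> float:
        d = np.diff(x)
        return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)

    result: dict[str, tuple] = {}
    for direction, sign in (("anodic", 1.0), ("cathodic", -1.0)):
        pot, cur = _segment_arrays(v, direction)
        if pot.size == 0:
            result[direction] = ((), (), ())
            continue
        smoothed = savgol_filter(cur, smooth_window, 2)
        rng = float(smoothed.max() - smoothed.min())
        prominence = max(prominence_fraction * rng, 5.0 * noise_sigma(cur))
        if prominence > 0:
            idx, _ = find_peaks(sign * smoothed, prominence=prominence)
        else:
            idx = np.array([], dtype=int)
        dpot, dval = deriv[direction]
        drng = float(dval.max() - dval.min())
        dprom = max(prominence_fraction * drng, 5.0 * noise_sigma(dval))
        if dprom > 0:
            didx, _ = find_peaks(sign * dval, prominence=dprom)
        else:
            didx = np.array([], dtype=int)
        result[direction] = (
            tuple(float(p) for p in pot[idx]),
            tuple(float(c) for c in cur[idx]),
            tuple(float(p) for p in dpot[didx]),
        )
    ox_pot, ox_h, an_infl = result["anodic"]
    red_pot, red_h, ca_infl = result["cathodic"]
    return PeakReport(
        oxidation_potentials_v=ox_pot,
        oxidation_heights_a=ox_h,
        reduction_potentials_v=red_pot,
        reduction_heights_a=red_h,
        anodic_inflections_v=an_infl,
        cathodic_inflections_v=ca_infl,
    )


def stage_batch_for_cv(
    time_h,
    voltage_v,
    rise_fraction: float = 0.10,
    plateau_fraction: float = 0.95,
    decline_fraction: float = 0.50,
    end_voltage_v: float = 0.02,
) -> CycleStages:
    """Pick the five canonical CV sampling times of one batch cycle.

    (1) first rise above ``rise_fraction`` of the maximum voltage, (2) the
    maximum itself, (3) the temporal midpoint of the plateau (samples within
    ``plateau_fraction`` of the maximum), (4) the first drop below
    ``decline_fraction`` of the maximum after the plateau, (5) cycle end:
    first sample under ``end_voltage_v`` after stage 4, else the last
    sample.  Undefined stages are NaN with an explanatory flag.
    """
    t = np.asarray(time_h, dtype=float)
    v = np.asarray(voltage_v, dtype=float)
    if t.size != v.size or t.size < 2:
        raise InsufficientDataError("need matching time/voltage series with >= 2 samples")
    vmax = float(v.max())
    flags: list[str] = []
    if vmax <= 0:
        raise DomainError("all-zero voltage trace has no stages")

    above = np.flatnonzero(v >= rise_fraction * vmax)
    rise = float(t[above[0]])
    i_max = int(np.argmax(v))
    maximum = float(t[i_max])
    if above[0] == i_max:
        flags.append("rise coincides with maximum (degenerate onset)")

    plateau_idx = np.flatnonzero(v >= plateau_fraction * vmax)
    if plateau_idx.size >= 2:
        plateau_mid = float(0.5 * (t[plateau_idx[0]] + t[plateau_idx[-1]]))
        plateau_end = int(plateau_idx[-1])
    else:
        plateau_mid = float(t[i_max])
        plateau_end = i_max
        flags.append("no plateau detected; stage 3 set to the maximum")
        warnings.warn("no voltage plateau detected; stage 3 is the maximum", StageWarning, stacklevel=2)

    after = np.flatnonzero((np.arange(t.size) > plateau_end) & (v < decline_fraction * vmax))
    if after.size:
        decline = float(t[after[0]])
        ends = np.flatnonzero((np.arange(t.size) >= after[0]) & (v < end_voltage_v))
        end = float(t[ends[0]]) if ends.size else float(t[-1])
        if not ends.size:
            flags.append("voltage never fell below the cycle-end threshold; stage 5 set to last sample")
    else:
        decline = float("nan")
        end = float("nan")
        flags.append("no decline detected; stages 4-5 undefined (truncated cycle?)")
    return CycleStages(
        rise_h=rise,
        maximum_h=maximum,
        plateau_mid_h=plateau_mid,
        decline_h=decline,
        end_h=end,
        flags=tuple(flags),
    )
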