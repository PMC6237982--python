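"""First-order nitrate-removal kinetics and volumetric removal rates.

Denitrification in donor-replete batch reactors is commonly well described
by C(t) = C0 * exp(-k t).  The default fit is log-linear ordinary least
squares on ln C — robust, closed-form, no initial guess — with values at or
below a detection floor excluded.  A nonlinear least-squares alternative
(on C itself) is available for series where near-zero tails would dominate
the log fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

__all__ = ["FirstOrderFit", "RemovalRate", "fit_first_order", "volumetric_removal_rate"]

#: Concentrations at/below this (mg/L) are treated as below detection.
DETECTION_FLOOR_MG_L = 0.1


@dataclass(frozen=True)
class FirstOrderFit:
    k: float  # rate constant, 1/h
    c0: float  # fitted initial concentration, mg/L
    r_squared: float
    method: Literal["log-linear", "nonlinear"]

    def predict(self, time_h: np.ndarray) -> np.ndarray:
        return self.c0 * np.exp(-self.k * np.asarray(time_h, dtype=float))

    def fraction_removed(self, duration_h: float) -> float:
        return 1.0 - float(np.exp(-self.k * duration_h))


@dataclass(frozen=True)
class RemovalRate:
    mg_n_per_l_h: float
    kg_n_per_m3_d: float


def fit_first_order(
    time_h,
    conc_mg_l,
    method: Literal["log-linear", "nonlinear"] = "log-linear",
    detection_floor_mg_l: float = DETECTION_FLOOR_MG_L,
) -> FirstOrderFit:
    """Fit C(t) = c0 * exp(-k t) to a concentration series.

    Log-linear: OLS of ln C on t over samples above the detection floor
    (needs >= 2 such samples).  Nonlinear: least squares on C directly,
    seeded from the log-linear fit, with k constrained >= 0.  A fitted
    positive slope (rising series) is clamped to k = 0.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_mg_l, dtype=float)
    if t.size != c.size:
        raise DomainError("time and concentration series must have equal length")
    if t.size < 3:
        raise InsufficientDataError("need at least 3 samples for a kinetic fit")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")
    if np.all(c <= detection_floor_mg_l):
        raise DegenerateDataError("all concentrations at/below the detection floor")

    mask = c > detection_floor_mg_l
    if mask.sum() < 2:
        raise DegenerateDataError("fewer than 2 samples above the detection floor")
    tm, cm = t[mask], c[mask]
    logc = np.log(cm)
    slope, intercept = np.polyfit(tm, logc, 1)
    k = max(-slope, 0.0)
    c0 = float(np.exp(intercept)) if k > 0 else float(np.exp(logc.mean()))

    if method == "log-linear":
        resid = logc - (np.log(c0) - k * tm)
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return FirstOrderFit(k=k, c0=c0, r_squared=min(max(r2, 0.0), 1.0), method="log-linear")
    if method == "nonlinear":
        popt, _ = curve_fit(
            lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
            t,
            c,
            p0=[max(c0, detection_floor_mg_l), k],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        c0_nl, k_nl = float(popt[0]), float(popt[1])
        resid = c - c0_nl * np.exp(-k_nl * t)
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        return FirstOrderFit(k=k_nl, c0=c0_nl, r_squared=r2, method="nonlinear")
    raise DomainError(f"unknown fit method {method!r}")


def volumetric_removal_rate(
    initial_mg_l: float,
    fraction_removed: float,
    duration_h: float,
) -> RemovalRate:
    """Average volumetric nitrogen removal rate over a window.

    rate = initial concentration x fraction removed / duration, reported
    both as mg N/(L h) and kg N/(m3 d) (the latter is the former x 0.024).
    E.g. 200 mg/L with 82.8% removed in 6 h gives 27.6 mg N/(L h) =
    0.66 kg N/(m3 d).
    """
    if duration_h <= 0:
        raise DomainError("duration must be > 0")
    if not 0.0 <= fraction_removed <= 1.0:
        raise DomainError("fraction_removed must lie in [0, 1]")
    if initial_mg_l < 0:
        raise DomainError("initial concentration must be >= 0")
    mg_l_h = initial_mg_l * fraction_removed / duration_h
    return RemovalRate(mg_n_per_l_h=mg_l_h, kg_n_per_m3_d=mg_l_h * 24.0 / 1000.0)
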