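# Methods

## Electron accounting model

One fed-batch cycle of a two-chamber MFC is treated as a closed electron
ledger. Substrate oxidation liberates a total charge

    C_t = ΔCOD [mg/L] × V_anolyte [L] × (1/1000/M_O2) × 4 × F,

using the COD convention that 1 mol O₂-equivalent accepts 4 mol e⁻
(M_O2 = 32 g/mol, F = 96 485 C/mol). For sodium acetate this is identical
to counting 8 e⁻ per mole oxidized (2 O₂ per acetate), and the two routes
are cross-checked in the tests to < 0.1%. ΔCOD is the endpoint difference
(first minus last measured sample); intermediate COD samples are read but
not used for `C_t`.

The ledger splits as `C_t = C_an + C_de + C_ot`:

* `C_an = ∫ V(t)/R_ext dt` by the trapezoidal rule with time in seconds.
  The trapezoid is exact for the piecewise-linear traces a 5-min logger
  produces, and its curvature error on exponentially decaying tails is
  O((Δt/τ)²/12) — negligible at the default sampling.
* `C_de` charges 5 e⁻ per mol nitrate-N removed, i.e. reduction fully to
  N₂. An optional nitrite correction subtracts 3 e⁻ per mol of residual
  nitrite-N (removal stalled at NO₂⁻ consumed only 2 of the 5); it is OFF
  by default because intermediates are typically below detection in the
  regime this package targets. Residual ammonium at cycle end raises a
  warning (dissimilatory reduction to NH₄⁺ would draw 8 e⁻/mol and is not
  modelled).
* `C_ot` is the exact residual. It is reported even when negative —
  a negative residual means the measured COD drop cannot fund the
  integrated current plus denitrification, which is a data-quality signal
  that clamping would hide.

Efficiencies: `CE = 100·C_an/C_t`, `CCE = 100·C_an/(C_t − C_de)`. CCE is
undefined (NaN) when denitrification accounts for the entire ledger.
Because the denominator only shrinks, `CCE ≥ CE` whenever `0 < C_de < C_t`;
this is enforced as a property test.

Net COD/N ratio (g COD consumed per g nitrate-N removed) has two modes:
**residual** (default) converts `C_t − C_an` back to COD mass — everything
the circuit did not collect is charged to the nitrogen line; and
**dissimilatory**, which converts only `C_de` and is the stoichiometric
constant 5·8/14 ≈ 2.86 regardless of data. Both are exposed because batch
data alone cannot distinguish which convention a given report used.

## Stoichiometric constants

`M_sodium_acetate` is fixed at 82.0 g/mol (not 82.03) and `M_N` at
14.0 g/mol so that the derived conversion is the conventional
1000·2·32/82 = 780.5 mg COD per g sodium acetate; using exact atomic
masses shifts the critical COD/N ratio only in the third decimal. All
constants are overridable from a JSON/YAML key-value file.

The biomass-inclusive heterotrophic denitrification reaction

    7.03 CH₃COO⁻ + 8.58 NO₃⁻ → 0.58 C₅H₇O₂N + 11.16 CO₂ + 8.58 OH⁻ + 7.74 H₂O + 4 N₂

yields the critical COD/N ratio
(7.03 · 82.0 · 0.7805) / (8.58 · 14.0) = 3.75 g COD per g N. As
conventionally printed, this equation balances C, N and O but is short
about 7.03 H and 7.03 negative charges on the right; the element/charge
audit reports the discrepancy rather than repairing the coefficients, and
the COD/N ratio uses them exactly as printed. The element-balance
tolerance for "balanced" is 0.05 formula units, matching two-decimal
coefficient rounding.

## Kinetics

Nitrate removal is modelled first-order, `C(t) = C₀ e^(−kt)`. The default
fit is ordinary least squares on ln C (closed form, no initial guess);
samples at or below a 0.1 mg/L detection floor are excluded so that
censored zeros cannot bend the line. A nonlinear least-squares variant
(scipy `curve_fit` on C, seeded from the log fit, k ≥ 0) is available for
series dominated by near-zero tails. A rising series clamps to k = 0.
The headline volumetric rate is the endpoint average,
`rate = C₀ · fraction_removed / duration`, reported in mg N L⁻¹ h⁻¹ and
kg N m⁻³ d⁻¹ (× 0.024).

## Electrochemistry

Polarization analysis takes the measured (R_ext, V) sweep, derives
I = V/R and densities normalized to the cathode area (default 7 cm²), and
reports the maximum power density from the measured points without
interpolation — matching discrete resistance sweeps as practiced. Internal
resistance is the negated least-squares slope of V on I (intercept =
open-circuit voltage). For a linear cell V = OCV − R_int·I the maximum
power density falls at R_ext = R_int (maximum power transfer); this is the
oracle the generator-based tests check over a random (OCV, R_int) grid.
Sweeps with fewer than 3 distinct resistances still yield a power density
but are flagged as not a located maximum.

CV first derivatives use Savitzky–Golay smoothing (order 2, default window
11 samples — the raw derivative of 1 mV-step data is noise-dominated)
followed by centered finite differences with one-sided endpoints. Peak
detection uses `scipy.signal.find_peaks` on the smoothed current, maxima
on the anodic sweep and minima on the cathodic, with prominence at least
`prominence_fraction` (default 0.05) of the segment's smoothed current
range **and** at least 5× a robust point-noise sigma estimated from first
differences. The noise floor makes a featureless noisy baseline return
zero detections while keeping the detector invariant to constant current
offsets and equivariant to current scaling. Inflection points are the
prominent extrema of dI/dE — one per redox wave — which is how two
overlapping oxidation waves are counted even when their peaks merge.
Anodic (oxidation) current is positive throughout.

Batch staging for CV sampling uses voltage thresholds that are design
choices, exposed as parameters: stage 1 at the first rise above 10% of the
cycle maximum, stage 2 at the maximum, stage 3 at the temporal midpoint of
the plateau (samples within 95% of the maximum), stage 4 at the first drop
below 50% after the plateau, stage 5 at the first sample under the 20 mV
cycle-end threshold. Degenerate traces (no plateau, monotone rise,
constant voltage) produce NaN stages with explanatory flags rather than
errors.

## Synthetic-data generator

The generator emulates the fed-batch regime the analysis assumes: anode
respiration and denitrification draw concurrently from one acetate pool
(donor limitation, not inhibition), so adding nitrate shortens the cycle
without touching the plateau voltage. Mechanics and defaults:

* reactor: 15 mL anolyte, 1 kΩ load, 7 cm² cathode; plateau 0.45 V;
  logging every 5 min; cycle ends below 20 mV;
* substrate: 780.5 mg/L COD (1 g/L sodium acetate);
* nitrate: first-order decline, default k = 0.29 h⁻¹ (the value implied by
  ~83% removal of 200 mg/L N within 6 h); default level 50 mg/L N, the
  mid-range condition where CCE peaks;
* `others_fraction` (default 0.10) of C_t goes to biomass/losses;
* measurement noise: multiplicative log-normal, mean 1, CV 2%, independent
  per channel and sample; everything is deterministic given (config, seed).

The plateau duration is solved (Brent's method) from the electron budget
`I·t_plateau + I·τ + C_de(t_plateau) = (1 − others_fraction)·C_t`, where
`I·τ` is the full analytic charge of the exponential voltage decay
(τ = 0.5 h; any positive constant satisfies the cycle-end rule). Nitrate
freezes when the donor is exhausted at plateau end. The emitted COD
trajectory is the cumulative-consumption curve, so recomputing the
partition from the emitted noise-free series reproduces the returned
ground truth to ~10⁻⁵ relative; the sample grid includes the exact
plateau-end corner, and the decay is recorded down to 1/20 of the end
threshold so the unrecorded tail charge is negligible. Within-cycle COD
samples are a synthetic construction — real studies typically measure COD
only at cycle boundaries — which is why the analysis defaults to endpoint
differences.

What the generator does **not** emulate: biofilm growth dynamics, pH and
mass-transfer effects, voltage rise at cycle start (the plateau starts at
t = 0), drifting internal resistance, or correlated sensor noise. Passing
round-trip tests therefore demonstrates the correctness of the accounting,
not the fidelity of any particular reactor.

## Problem sizes and tolerances in the test suite

The acceptance-style tests use 100 seeds for CE recovery (target-CE-40%
configuration: others_fraction 0.35, 68.3 mg/L N; worst-case error < 3
CE points at 2% noise, < 0.5 noise-free), 100 simulated series for rate
recovery (k ∈ [0.05, 0.5] h⁻¹, median relative error < 5%), a 50-draw
(OCV, R_int) grid for max power transfer, and ±5 mV for redox-peak
recovery at a 1 mV step. Property tests (hypothesis) run derandomized
with 50 examples. The entire suite completes in a few seconds on one CPU.

## Known limitations

* The electron ledger assumes all nitrate loss is dissimilatory reduction
  to N₂ unless the nitrite correction is enabled; assimilatory N uptake is
  not separated from `C_ot`.
* Endpoint-difference `C_t` inherits the full measurement error of two COD
  samples; with 2% per-sample noise this dominates the CE recovery error.
* The V–I regression assumes ohmic behavior; activation/concentration
  overpotential curvature biases the internal-resistance estimate on real
  polarization data.
* Multi-cycle splitting relies on the 20 mV / 3-sample debounce rule and
  will not separate cycles whose troughs never reach 20 mV.
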