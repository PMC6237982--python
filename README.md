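# mfcflux

Electron-flux accounting for microbial fuel cells (MFCs) that perform
simultaneous denitrification and electricity generation.

In a fed-batch MFC whose anode biofilm both respires on the electrode and
denitrifies, the electrons liberated by substrate (acetate/COD) oxidation
split three ways. `mfcflux` implements that bookkeeping as a tested
pipeline for wastewater/bioelectrochemistry researchers:

* **Electron balance.** The total charge liberated in one cycle is
  `C_t = ΔCOD · V · (4F / M_O2)` (1 mol O₂-equivalent COD accepts 4 e⁻).
  The circuit collects `C_an = ∫ V(t)/R_ext dt`; denitrification consumes
  `C_de` at 5 e⁻ per mol nitrate-N reduced to N₂; the residual
  `C_ot = C_t − C_an − C_de` covers biomass synthesis and losses.
  Coulombic efficiency `CE = C_an/C_t × 100%`; corrected coulombic
  efficiency `CCE = C_an/(C_t − C_de) × 100%` excludes the denitrification
  draw from the denominator.
* **Stoichiometry.** COD equivalents (780.5 mg COD per g sodium acetate,
  from 2 mol O₂ per mol acetate), half-reaction element/charge audits, and
  the critical COD/N mass ratio of biomass-inclusive heterotrophic
  denitrification (7.03 CH₃COO⁻ : 8.58 NO₃⁻ → 3.75 g COD per g N).
* **Kinetics.** First-order nitrate-removal fits `C(t) = C₀ e^(−kt)` and
  volumetric removal rates in kg N m⁻³ d⁻¹ / mg N L⁻¹ h⁻¹.
* **Electrochemistry.** Polarization sweeps → power/current densities
  normalized to cathode area, maximum power density and internal
  resistance; cyclic voltammetry → Savitzky–Golay-smoothed first
  derivatives, redox-peak and inflection-point detection, and five-stage
  batch segmentation for CV sampling.
* **Synthetic data.** A deterministic generator of batch cycles (voltage
  plateau + exponential decay, first-order nitrate decline, electron-exact
  COD trajectory, log-normal measurement noise), linear-cell polarization
  sweeps, and Gaussian-wave voltammograms, each returning ground truth so
  every stage is testable end-to-end.

## Worked example

Simulate one cycle (15 mL anolyte, 1 kΩ load, 780.5 mg/L COD, 50 mg/L
nitrate-N, 2% measurement noise) and analyze it:

```bash
mfcflux simulate --seed 7 --out cycle.csv --truth-out truth.json
mfcflux balance cycle.csv
```

```json
{
  "cycle_0": {
    "c_an": 101.02, "c_de": 26.34, "c_ot": 15.34, "c_t": 142.70,
    "ce_pct": 70.79, "cce_pct": 86.82,
    "fractions": {"anode_respiration": 0.708,
                  "anodic_denitrification": 0.185, "others": 0.107},
    "net_cod_n_ratio": 4.52
  }
}
```

Of the 142.7 C liberated by the COD drop, 101.0 C reached the circuit
(CE 70.8%), 26.3 C reduced nitrate to N₂, and 15.3 C went to biomass and
losses; excluding the denitrification draw lifts the efficiency to
CCE 86.8%. `mfcflux kinetics cycle.csv` recovers the nitrate decay
constant `k = 0.290 h⁻¹` (R² = 0.9999) from the same file. The full
pipeline (`mfcflux report --inputs DIR --out OUT`) writes per-cycle
balances, kinetics and a summary table as JSON + CSV.

As a library:

```python
from mfcflux import critical_cod_n_ratio, volumetric_removal_rate

critical_cod_n_ratio()                      # 3.746 g COD per g N
volumetric_removal_rate(200, 0.828, 6.0)    # 0.662 kg N m^-3 d^-1
```

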