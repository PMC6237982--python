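"""Polarization analysis, CV derivatives/peaks, and batch staging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mfcflux.electrochem import (
    PolarizationCurve,
    Voltammogram,
    cv_first_derivative,
    detect_redox_peaks,
    polarization_analysis,
    stage_batch_for_cv,
)
from mfcflux.exceptions import (
    DomainError,
    InconsistentDataError,
    InsufficientDataError,
    ParameterError,
    StageWarning,
)
from mfcflux.simulate import CVPeak, simulate_cv, simulate_polarization

SWEEP = (100, 150, 200, 300, 500, 1000, 5000)


class TestPolarization:
    def test_linear_cell_max_power_transfer(self):
        """V = 0.7 - 200 I puts the MPD at R_ext = 200 Ohm: 0.875 W/m2, 2.5 A/m2."""
        curve = simulate_polarization(0.7, 200.0, resistances=SWEEP)
        report = polarization_analysis(curve)
        assert report.resistance_at_mpd_ohm == 200.0
        assert report.mpd_w_m2 == pytest.approx(0.875, abs=1e-9)
        assert report.current_density_at_mpd_a_m2 == pytest.approx(2.5, abs=1e-9)
        assert report.internal_resistance_ohm == pytest.approx(200.0, rel=1e-6)
        assert report.open_circuit_voltage_v == pytest.approx(0.7, rel=1e-6)
        assert report.is_located_maximum

    def test_single_point_power_flagged_as_non_maximum(self):
        curve = PolarizationCurve([1000.0], [0.45])
        report = polarization_analysis(curve)
        assert report.mpd_w_m2 == pytest.approx(0.45**2 / 1000 / 7e-4, abs=1e-6)
        assert not report.is_located_maximum
        assert np.isnan(report.internal_resistance_ohm)

    def test_zero_voltage_curve_has_zero_mpd(self):
        curve = PolarizationCurve(list(SWEEP), [0.0] * len(SWEEP))
        assert polarization_analysis(curve).mpd_w_m2 == 0.0

    def test_conflicting_duplicate_resistances_rejected(self):
        with pytest.raises(InconsistentDataError):
            polarization_analysis(PolarizationCurve([100.0, 100.0, 200.0], [0.3, 0.4, 0.5]))

    def test_power_density_is_voltage_times_current_density(self):
        curve = simulate_polarization(0.7, 150.0, resistances=SWEEP)
        assert curve.power_density_w_m2 == pytest.approx(
            curve.voltage_v * curve.current_density_a_m2
        )

    @given(
        ocv=st.floats(min_value=0.2, max_value=1.2),
        r_int=st.sampled_from([100.0, 150.0, 200.0, 300.0, 500.0, 1000.0]),
    )
    def test_mpd_at_internal_resistance_over_grid(self, ocv, r_int):
        """Max power transfer: the sweep point closest to R_int wins, any OCV."""
        sweep = (100, 150, 200, 300, 500, 1000, 2000, 5000)
        curve = simulate_polarization(ocv, r_int, resistances=sweep)
        report = polarization_analysis(curve)
        assert report.resistance_at_mpd_ohm == r_int

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(DomainError):
            PolarizationCurve([0.0, 100.0], [0.1, 0.2])


def two_peak_cv():
    return simulate_cv(
        [
            CVPeak(-0.21, 1.0e-4, 0.04, "anodic"),
            CVPeak(-0.05, 0.8e-4, 0.04, "anodic"),
            CVPeak(-0.185, 0.9e-4, 0.04, "cathodic"),
        ]
    )


class TestCvDerivative:
    def test_linear_current_has_constant_derivative(self):
        pot = np.linspace(-0.6, 0.2, 801)
        v = Voltammogram(np.concatenate([pot, pot[::-1]]), np.concatenate([3e-4 * pot + 1e-5, 3e-4 * pot[::-1] - 1e-5]))
        deriv = cv_first_derivative(v)
        for _, d in deriv.values():
            assert d == pytest.approx(3e-4, rel=1e-6)

    def test_gaussian_peak_derivative_crosses_zero_at_center(self):
        v = simulate_cv([CVPeak(-0.21, 1e-4, 0.04, "anodic")], baseline_capacitive_a=0.0)
        pot, d = cv_first_derivative(v)["anodic"]
        sign_change = np.flatnonzero(np.diff(np.sign(d)) < 0)
        crossing = pot[sign_change[0]]
        assert crossing == pytest.approx(-0.21, abs=0.0015)

    def test_overlapping_waves_give_two_anodic_inflections(self):
        """Two merged oxidation waves still show two dI/dE maxima; one reduction."""
        report = detect_redox_peaks(two_peak_cv(), prominence_fraction=0.05)
        assert len(report.anodic_inflections_v) == 2
        assert len(report.cathodic_inflections_v) == 1

    def test_window_longer_than_segment_rejected(self):
        v = simulate_cv([], step_v=0.01)
        with pytest.raises(ParameterError):
            cv_first_derivative(v, smooth_window=999)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            cv_first_derivative(two_peak_cv(), smooth_window=10)

    def test_short_segment_rejected(self):
        pot = np.linspace(-0.6, 0.2, 20)
        v = Voltammogram(pot, np.zeros_like(pot))
        with pytest.raises(InsufficientDataError):
            cv_first_derivative(v, smooth_window=5)


class TestPeakDetection:
    def test_reference_redox_pair_recovered(self):
        """Oxidation at -0.21 V / reduction at -0.185 V located within 5 mV."""
        v = simulate_cv(
            [CVPeak(-0.21, 1e-4, 0.02, "anodic"), CVPeak(-0.185, 9e-5, 0.02, "cathodic")]
        )
        report = detect_redox_peaks(v, prominence_fraction=0.1)
        assert len(report.oxidation_potentials_v) == 1
        assert len(report.reduction_potentials_v) == 1
        assert report.oxidation_potentials_v[0] == pytest.approx(-0.21, abs=0.005)
        assert report.reduction_potentials_v[0] == pytest.approx(-0.185, abs=0.005)

    def test_noisy_flat_baseline_yields_no_peaks(self):
        v = simulate_cv([], baseline_capacitive_a=1e-5, noise_a=1e-7, seed=5)
        report = detect_redox_peaks(v, prominence_fraction=0.1)
        assert report.oxidation_potentials_v == ()
        assert report.reduction_potentials_v == ()

    def test_peak_scaling_equivariance_and_offset_invariance(self):
        base = simulate_cv([CVPeak(-0.21, 1e-4, 0.02, "anodic")])
        scaled = Voltammogram(base.potential_v, base.current_a * 2, segment=base.segment)
        offset = Voltammogram(base.potential_v, base.current_a + 5e-4, segment=base.segment)
        r0 = detect_redox_peaks(base, 0.1)
        r_scaled = detect_redox_peaks(scaled, 0.1)
        r_offset = detect_redox_peaks(offset, 0.1)
        assert r_scaled.oxidation_potentials_v == r0.oxidation_potentials_v
        assert r_scaled.oxidation_heights_a[0] == pytest.approx(2 * r0.oxidation_heights_a[0])
        assert r_offset.oxidation_potentials_v == r0.oxidation_potentials_v

    def test_bad_prominence_fraction_rejected(self):
        with pytest.raises(ParameterError):
            detect_redox_peaks(two_peak_cv(), prominence_fraction=1.5)


def trapezoid_voltage(n=200):
    t = np.linspace(0.0, 20.0, n)
    v = np.interp(t, [0, 2, 4, 14, 16, 18, 20], [0.0, 0.2, 0.45, 0.45, 0.2, 0.01, 0.0])
    return t, v


class TestStaging:
    def test_trapezoidal_cycle_stages_in_order(self):
        t, v = trapezoid_voltage()
        stages = stage_batch_for_cv(t, v)
        s = stages.as_tuple()
        assert all(np.isfinite(s))
        assert s[0] <= s[1] < s[2] < s[3] < s[4]

    def test_monotone_rise_leaves_decline_undefined(self):
        t = np.linspace(0.0, 5.0, 50)
        stages = stage_batch_for_cv(t, 0.09 * t)
        assert np.isnan(stages.decline_h) and np.isnan(stages.end_h)
        assert any("stages 4-5" in f for f in stages.flags)

    def test_constant_voltage_degenerate_onset_flagged(self):
        t = np.linspace(0.0, 5.0, 50)
        stages = stage_batch_for_cv(t, np.full_like(t, 0.4))
        assert stages.rise_h == stages.maximum_h
        assert any("degenerate" in f for f in stages.flags)

    def test_no_plateau_warns(self):
        t = np.linspace(0.0, 10.0, 101)
        v = 0.45 * np.exp(-0.5 * (t - 5.0) ** 2)  # single sharp hump
        with pytest.warns(StageWarning):
            stage_batch_for_cv(t, v, plateau_fraction=0.999999)

    def test_all_zero_voltage_rejected(self):
        with pytest.raises(DomainError):
            stage_batch_for_cv([0.0, 1.0], [0.0, 0.0])
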