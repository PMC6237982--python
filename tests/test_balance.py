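"""Electron partition, CE/CCE, and net COD/N accounting."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from mfcflux.balance import (
    BatchCycleRecord,
    ElectronBalance,
    ReactorSpec,
    electron_fractions,
    integrate_current,
    net_cod_n_ratio,
    partition,
    total_electrons,
)
from mfcflux.exceptions import (
    ConservationWarning,
    DataQualityWarning,
    DomainError,
    InsufficientDataError,
)
from mfcflux.simulate import SimulationConfig, simulate_batch_cycle
from mfcflux.stoichiometry import cod_equivalent_of_charge, electrons_from_nitrate


def make_cycle(
    hours=10.0,
    n=121,
    voltage=0.45,
    cod0=780.5,
    cod1=0.0,
    no3_0=0.0,
    no3_1=0.0,
    **reactor,
):
    """Hand-built cycle with constant (or callable) voltage and linear chemistry."""
    t = np.linspace(0.0, hours, n)
    v = voltage(t) if callable(voltage) else np.full(n, float(voltage))
    return BatchCycleRecord(
        time_h=t,
        voltage_v=v,
        cod_mg_l=np.linspace(cod0, cod1, n),
        no3n_mg_l=np.linspace(no3_0, no3_1, n),
        reactor=ReactorSpec(**reactor),
    )


class TestRecordValidation:
    def test_non_monotone_time_rejected_with_row(self):
        with pytest.raises(DomainError, match="row 2"):
            BatchCycleRecord(
                time_h=[0.0, 1.0, 1.0],
                voltage_v=[0.4, 0.4, 0.4],
                cod_mg_l=[700, 400, 100],
                no3n_mg_l=[50, 25, 0],
            )

    def test_negative_voltage_rejected(self):
        with pytest.raises(DomainError, match="voltage"):
            make_cycle(voltage=lambda t: np.where(t > 5, -0.1, 0.4))

    def test_endpoint_chemistry_required(self):
        with pytest.raises(DomainError, match="cod_mg_l"):
            BatchCycleRecord(
                time_h=[0.0, 1.0],
                voltage_v=[0.4, 0.4],
                cod_mg_l=[np.nan, 100.0],
                no3n_mg_l=[50.0, 10.0],
            )

    def test_nan_means_unmeasured_in_the_middle(self):
        rec = BatchCycleRecord(
            time_h=[0.0, 1.0, 2.0],
            voltage_v=[0.4, 0.4, 0.4],
            cod_mg_l=[700.0, np.nan, 100.0],
            no3n_mg_l=[50.0, np.nan, 5.0],
        )
        assert rec.delta("cod_mg_l") == 600.0


class TestIntegrateCurrent:
    def test_constant_voltage_closed_form(self):
        # 0.45 V across 1 kOhm for 10 h = 4.5e-4 A * 36000 s
        assert integrate_current(make_cycle()) == pytest.approx(16.2, abs=1e-9)

    def test_zero_voltage_gives_zero_charge(self):
        assert integrate_current(make_cycle(voltage=0.0)) == 0.0

    def test_linear_ramp_is_half_the_constant_case(self):
        ramp = make_cycle(voltage=lambda t: 0.45 * t / 10.0)
        assert integrate_current(ramp) == pytest.approx(8.1, abs=1e-9)

    def test_single_sample_insufficient(self):
        with pytest.raises(InsufficientDataError):
            integrate_current(make_cycle(n=1))


class TestTotalElectrons:
    def test_full_cod_drop_in_15_ml(self):
        assert total_electrons(make_cycle(cod0=780.5, cod1=0.0)) == pytest.approx(141.2, abs=0.1)

    def test_no_cod_change_gives_zero(self):
        assert total_electrons(make_cycle(cod0=500.0, cod1=500.0)) == 0.0

    def test_half_volume_halves_charge(self):
        full = total_electrons(make_cycle())
        half = total_electrons(make_cycle(anolyte_volume_l=0.0075))
        assert half == pytest.approx(full / 2)

    def test_cod_increase_warns_and_counts_zero(self):
        rising = make_cycle(cod0=400.0, cod1=450.0)
        with pytest.warns(DataQualityWarning):
            assert total_electrons(rising) == 0.0


class TestPartition:
    def test_round_trip_on_simulated_cycle_with_known_partition(self):
        """Config tuned for CE ~40%, c_de ~25% of c_t recovers both; others ~0.35."""
        config = SimulationConfig(noise_cv=0.0, others_fraction=0.35, initial_no3n_mg_l=68.3)
        record, truth = simulate_batch_cycle(config, seed=3)
        bal = partition(record)
        assert truth.ce_pct == pytest.approx(40.0, abs=1.0)
        assert bal.ce_pct == pytest.approx(truth.ce_pct, abs=2.0)
        assert bal.fractions["others"] == pytest.approx(0.35, abs=0.01)
        assert bal.fractions["anodic_denitrification"] == pytest.approx(0.25, abs=0.01)

    def test_no_nitrate_control_has_cce_equal_ce(self):
        record, _ = simulate_batch_cycle(SimulationConfig(noise_cv=0.0, initial_no3n_mg_l=0.0), seed=2)
        bal = partition(record)
        assert bal.c_de == 0.0
        assert bal.cce_pct == bal.ce_pct

    def test_cce_undefined_when_denitrification_consumes_everything(self):
        bal = ElectronBalance(c_t=100.0, c_an=0.0, c_de=100.0)
        assert math.isnan(bal.cce_pct)

    def test_negative_residual_warns_without_clamping(self):
        # current integral exceeds what the COD drop can supply
        rec = make_cycle(cod0=100.0, cod1=95.0, voltage=0.45)
        with pytest.warns(ConservationWarning):
            bal = partition(rec)
        assert bal.c_ot < 0
        assert bal.c_t == pytest.approx(bal.c_an + bal.c_de + bal.c_ot)

    def test_residual_ammonium_triggers_quality_warning(self):
        rec = make_cycle(no3_0=50.0, no3_1=0.0)
        rec.nh4n_mg_l = np.full(rec.n_samples, 2.0)
        with pytest.warns(DataQualityWarning, match="ammonium"):
            partition(rec)

    def test_conservation_is_exact_by_construction(self, noisy_cycle):
        record, _ = noisy_cycle
        bal = partition(record)
        assert bal.c_an + bal.c_de + bal.c_ot == pytest.approx(bal.c_t, abs=1e-12)


class TestFractions:
    @pytest.mark.parametrize(
        "c_t, c_an, c_de, expected",
        [
            (100.0, 60.0, 30.0, (0.60, 0.30, 0.10)),
            (100.0, 100.0, 0.0, (1.0, 0.0, 0.0)),
        ],
    )
    def test_fraction_arithmetic(self, c_t, c_an, c_de, expected):
        f = electron_fractions(ElectronBalance(c_t, c_an, c_de))
        assert (
            f["anode_respiration"],
            f["anodic_denitrification"],
            f["others"],
        ) == pytest.approx(expected)

    def test_fractions_sum_to_one_on_simulated_cycle(self, noise_free_cycle):
        record, _ = noise_free_cycle
        f = partition(record).fractions
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_charge_rejected(self):
        with pytest.raises(DomainError):
            electron_fractions(ElectronBalance(0.0, 0.0, 0.0))

    @given(
        c_t=st.floats(min_value=1.0, max_value=1e4),
        f_an=st.floats(min_value=0.0, max_value=1.0),
        f_de=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_cce_at_least_ce_when_denitrification_draws(self, c_t, f_an, f_de):
        """CCE >= CE whenever 0 < c_de < c_t: the denominator only shrinks."""
        assume(0.0 < f_de < 1.0)
        bal = ElectronBalance(c_t=c_t, c_an=f_an * c_t, c_de=f_de * c_t)
        assert bal.cce_pct >= bal.ce_pct

    @given(st.floats(min_value=0.01, max_value=0.99), st.floats(min_value=0.01, max_value=0.99))
    def test_cce_monotone_in_denitrification_charge(self, f_de_lo, f_de_hi):
        assume(f_de_lo < f_de_hi)
        c_t, c_an = 100.0, 0.5
        lo = ElectronBalance(c_t, c_an, f_de_lo * (c_t - c_an)).cce_pct
        hi = ElectronBalance(c_t, c_an, f_de_hi * (c_t - c_an)).cce_pct
        assert hi > lo


class TestNetCodN:
    def test_dissimilatory_mode_is_stoichiometric_constant(self):
        rec = make_cycle(no3_0=50.0, no3_1=0.0)
        # 5 e-/mol N at 8 g COD per mol e- pair: 5 * 8 / 14 = 2.857 g COD/g N
        assert net_cod_n_ratio(rec, "dissimilatory") == pytest.approx(2.86, abs=0.01)

    def test_residual_mode_on_constructed_cycle(self):
        """Cycle built so that (c_t - c_an) is exactly 3.75 g COD per g N removed."""
        n_removed_mg = 50.0 * 0.015
        target_charge = 3.75 * n_removed_mg / cod_equivalent_of_charge(1.0)
        hours, r = 10.0, 1000.0
        # constant voltage whose integral leaves exactly target_charge unrecovered
        c_t = target_charge + 16.2
        delta_cod = cod_equivalent_of_charge(c_t) / 0.015
        rec = make_cycle(hours=hours, cod0=delta_cod, cod1=0.0, no3_0=50.0, no3_1=0.0)
        assert net_cod_n_ratio(rec, "residual") == pytest.approx(3.75, abs=0.05)

    def test_full_recovery_gives_zero_residual_ratio(self):
        # all liberated charge collected by the circuit; nothing left over
        c_an = 16.2
        delta_cod = cod_equivalent_of_charge(c_an) / 0.015
        rec = make_cycle(cod0=delta_cod, cod1=0.0, no3_0=1.0, no3_1=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConservationWarning)
            assert net_cod_n_ratio(rec, "residual") == pytest.approx(0.0, abs=0.05)

    def test_zero_removal_rejected(self):
        with pytest.raises(DomainError):
            net_cod_n_ratio(make_cycle(no3_0=50.0, no3_1=50.0), "residual")

    def test_unknown_mode_rejected(self):
        with pytest.raises(DomainError):
            net_cod_n_ratio(make_cycle(no3_0=50.0, no3_1=0.0), "both")
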