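import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mnpkin as m
from mnpkin.simulate import (
    DegenerateKineticsError,
    langmuir_theta,
    langmuir_theta_ode,
    simulate_calibration_plate,
    two_compartment_theta,
)


class TestLangmuirTheta:
    def test_zero_at_onset_and_before(self, truth):
        assert langmuir_theta(60.0, 1e-9, truth, t0=60.0) == 0.0
        assert langmuir_theta(10.0, 1e-9, truth, t0=60.0) == 0.0

    def test_equilibrium_half_coverage_at_kd(self, truth):
        # C = K_D^bi  =>  theta_eq = 1/2
        theta = langmuir_theta(1e9, truth.kd_bi, truth)
        assert theta == pytest.approx(0.5, rel=1e-9)

    def test_one_time_constant_reaches_1_minus_inv_e(self):
        truth = m.KineticTruth(1e6, 1e-4)
        C = 1e-9
        k_obs = truth.k_obs(C)
        theta_eq = truth.kon_bi * C / k_obs
        val = langmuir_theta(1.0 / k_obs, C, truth, t0=0.0)
        assert val == pytest.approx(theta_eq * (1 - np.exp(-1)), rel=1e-12)

    @pytest.mark.parametrize("kon", [1e6, 3e6, 1e7])
    @pytest.mark.parametrize("koff", [1e-4, 1e-3, 1e-2])
    def test_closed_form_matches_ode_integration(self, kon, koff):
        """Independent ODE oracle: dtheta/dt = kon*C*(1-theta) - koff*theta."""
        truth = m.KineticTruth(kon, koff)
        t = np.linspace(0, 500, 101)
        closed = langmuir_theta(t, 1e-9, truth, t0=0.0)
        ode = langmuir_theta_ode(t, 1e-9, truth, t0=0.0)
        assert np.max(np.abs(closed - ode)) < 1e-8

    def test_degenerate_kinetics_raises(self):
        truth = m.KineticTruth(1e6, 0.0)
        with pytest.raises(DegenerateKineticsError):
            langmuir_theta(100.0, 0.0, truth)

    @given(
        kon=st.floats(1e4, 1e8), koff=st.floats(0, 1e-2),
        c=st.floats(1e-12, 1e-8), t=st.floats(0, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_coverage_bounded_and_increasing_in_concentration(self, kon, koff, c, t):
        truth = m.KineticTruth(kon, koff)
        th = langmuir_theta(t, c, truth)
        assert 0.0 <= th <= 1.0
        if t > 0:
            assert langmuir_theta(t, 2 * c, truth) >= th


class TestSimulateDataset:
    def test_zero_noise_equals_closed_form(self, layout, batch, truth, clean_dataset):
        for tr in clean_dataset:
            if tr.bait in ("PD-L1", "PD-L2"):
                conc = batch.channel_concentrations[tr.channel]
                expected = langmuir_theta(tr.times, conc, truth, layout.onset_time)
                np.testing.assert_allclose(tr.signals, expected, rtol=1e-12, atol=0)
            elif tr.role == "probe":
                assert np.all(tr.signals == 0.0)

    def test_non_binders_flat_and_no_baseline_step(self, clean_dataset):
        flats = [t for t in clean_dataset if t.bait in ("mIgG", "BSA", "REF", "PD-1", "B7-1")]
        assert flats
        for t in flats:
            assert np.all(t.signals == 0.0)

    def test_channel_dilution_slows_binding(self, clean_dataset):
        """Binder traces at 100% rise faster than at 25%."""
        ch0 = next(t for t in clean_dataset if t.channel == 0 and t.bait == "PD-L1")
        ch3 = next(t for t in clean_dataset if t.channel == 3 and t.bait == "PD-L1")
        late = ch0.times >= 70
        assert np.all(ch0.signals[late] > ch3.signals[late])

    def test_sixteen_traces_per_channel(self, clean_dataset, layout):
        for ch in range(layout.n_channels):
            assert sum(t.channel == ch for t in clean_dataset) == 16

    def test_same_seed_bit_identical(self, layout, batch, truth_map):
        nm = m.NoiseModel(0.02, 0.05, seed=11)
        a = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        b = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.signals, y.signals)

    def test_duplicates_identical_when_amp_cv_zero(self, layout, batch, truth_map):
        nm = m.NoiseModel(0.0, 0.0, seed=3)
        traces = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        d0 = next(t for t in traces if t.channel == 0 and t.sensor == 2)
        d1 = next(t for t in traces if t.channel == 0 and t.sensor == 3)
        assert d0.bait == d1.bait
        np.testing.assert_array_equal(d0.signals, d1.signals)

    def test_unknown_bait_in_truth_map_rejected(self, layout, batch, truth, noiseless):
        with pytest.raises(ValueError, match="absent from layout"):
            m.simulate_dataset(layout, batch, {"nonesuch": truth}, noiseless, 520.0)

    def test_short_duration_rejected(self, layout, batch, truth_map, noiseless):
        with pytest.raises(ValueError, match="duration"):
            m.simulate_dataset(layout, batch, truth_map, noiseless, 100.0)


class TestTwoCompartment:
    def test_converges_to_langmuir_as_transport_vanishes(self, truth):
        t = np.arange(0, 520, 5.5)
        lang = langmuir_theta(t, 1e-9, truth, 60.0)
        tc = two_compartment_theta(t, 1e-9, truth, da_local=1e-9, t0=60.0)
        assert np.max(np.abs(tc - lang)) < 1e-6

    def test_transport_limitation_slows_apparent_binding(self, truth):
        from mnpkin.fitting import ExponentialAssociationFitter

        t = np.arange(0, 520, 5.5)
        th = two_compartment_theta(t, 1e-9, truth, da_local=10.0, t0=60.0)
        est = ExponentialAssociationFitter(t0=60.0).fit(t, th)
        assert est.k_obs_ < truth.k_obs(1e-9)

    @pytest.mark.parametrize("da", [0.0, 0.5, 5.0, 50.0])
    def test_coverage_stays_in_unit_interval(self, truth, da):
        t = np.linspace(0, 2000, 200)
        th = two_compartment_theta(t, 5e-9, truth, da_local=da, t0=0.0)
        assert np.all((th >= 0) & (th <= 1))

    def test_simulate_two_compartment_dispatch(self, layout, batch, truth_map, noiseless):
        traces = m.simulate_two_compartment(
            layout, batch, truth_map, k_m=1e-3, b_m=1e-9, noise=noiseless,
            duration=520.0,
        )
        assert len(traces) == 64
        with pytest.raises(ValueError, match="k_M"):
            m.simulate_two_compartment(
                layout, batch, truth_map, k_m=0.0, b_m=1e-9, noise=noiseless,
                duration=520.0,
            )


class TestCalibrationPlate:
    def test_noiseless_points_on_the_line(self):
        plate = simulate_calibration_plate(0.5, 0.05, noise_sd=0.0)
        std = plate[plate.role == "standard"]
        np.testing.assert_allclose(
            std.absorbance_425nm, 0.5 * std.concentration_nM + 0.05, rtol=1e-15
        )

    def test_default_standards_in_duplicate(self):
        plate = simulate_calibration_plate(0.5, 0.05, replicates=2)
        assert (plate.role == "standard").sum() == 14
        assert (plate.role == "unknown").sum() == 2
        assert plate[plate.role == "unknown"].concentration_nM.isna().all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration_plate(0.5, 0.05, noise_sd=-1.0)
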