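import numpy as np
import pytest

import mnpkin as m
from mnpkin.fitting import (
    ExponentialAssociationFitter,
    FittingConfigError,
    WindowingError,
    aggregate_duplicates,
    detect_onset,
    dissociation_phase_fit,
    fit_all_probes,
)
from mnpkin.simulate import langmuir_theta


def make_trace(times, signals, channel=0, sensor=0, bait="PD-L1", role="probe"):
    return m.BindingTrace(channel, sensor, bait, times, signals, role=role)


class TestSubtractReference:
    def test_reference_traces_become_zero(self, clean_dataset, layout):
        out = m.subtract_reference(clean_dataset, layout)
        for t in out:
            if t.consumed_as_reference:
                np.testing.assert_array_equal(t.signals, 0.0)
                assert t.role == "reference"

    def test_constant_offset_removed_exactly(self, layout, clean_dataset):
        shifted = [t.with_signals(t.signals + 0.37) for t in clean_dataset]
        out = m.subtract_reference(shifted, layout)
        ref = m.subtract_reference(clean_dataset, layout)
        for a, b in zip(out, ref):
            np.testing.assert_allclose(a.signals, b.signals, atol=1e-12)

    def test_common_mode_drift_leaves_kobs_unchanged(self, layout, batch, truth_map):
        """Arbitrary channel-common drift cancels in reference subtraction."""
        nm = m.NoiseModel(0.02, 0.05, seed=5)
        traces = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        drift = 0.3 * np.sin(traces[0].times / 40.0) + 0.002 * traces[0].times
        drifted = [t.with_signals(t.signals + drift) for t in traces]

        fits_a = fit_all_probes(m.subtract_reference(traces, layout), 60.0)
        fits_b = fit_all_probes(m.subtract_reference(drifted, layout), 60.0)
        checked = 0
        for a, b in zip(fits_a, fits_b):
            if a.bait in ("PD-L1", "PD-L2") and a.converged:
                assert b.k_obs == pytest.approx(a.k_obs, rel=1e-6)
                checked += 1
        assert checked >= 8

    def test_channel_without_reference_rejected(self, clean_dataset):
        probes_only = [t for t in clean_dataset if t.role == "probe"]
        with pytest.raises(FittingConfigError, match="channel 0"):
            m.subtract_reference(probes_only, m.default_layout())

    def test_negative_controls_used_when_no_dedicated_reference(self, layout, clean_dataset):
        no_ref = [t for t in clean_dataset if t.role != "reference"]
        out = m.subtract_reference(no_ref, layout)
        consumed = {t.bait for t in out if t.consumed_as_reference}
        assert consumed == {"mIgG", "BSA"}


class TestSynchronizeOnset:
    def test_aligned_traces_are_identity(self, clean_dataset, layout):
        out, t0 = m.synchronize_onset(clean_dataset, layout)
        assert t0 == layout.onset_time
        for a, b in zip(out, clean_dataset):
            np.testing.assert_array_equal(a.times, b.times)

    def test_injected_lag_realigned_within_one_sample(self, layout, batch, truth_map):
        nm = m.NoiseModel(0.02, 0.0, seed=9)
        traces = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        lag = 2 * layout.sampling_interval
        lagged = [
            t.with_times(t.times + lag) if t.channel == 1 else t for t in traces
        ]
        base = {ch: detect_onset(traces, ch) for ch in range(4)}
        after = {ch: detect_onset(lagged, ch) for ch in range(4)}
        assert after[1] - base[1] == pytest.approx(lag, abs=layout.sampling_interval)
        synced, _ = m.synchronize_onset(lagged, layout, auto=True)
        re_detected = detect_onset(synced, 1)
        assert abs(re_detected - layout.onset_time) <= layout.sampling_interval

    def test_flat_traces_fall_back_with_warning(self, layout):
        times = np.arange(0, 520, 5.5)
        flat = [make_trace(times, np.zeros_like(times), channel=0, sensor=s)
                for s in range(2)]
        with pytest.warns(UserWarning, match="undetectable"):
            out, t0 = m.synchronize_onset(flat, layout, auto=True)
        assert t0 == layout.onset_time
        np.testing.assert_array_equal(out[0].times, times)

    def test_onset_outside_span_rejected(self, layout):
        times = np.arange(0, 30, 5.5)
        tr = [make_trace(times, np.zeros_like(times))]
        with pytest.raises(WindowingError):
            m.synchronize_onset(tr, layout, onset_time=100.0)


class TestFitBindingCurve:
    def test_zero_noise_exact_recovery(self):
        times = np.arange(0, 520, 5.5)
        A, k = 1.0, 5e-3
        sig = np.where(times < 60, 0.0, A * (1 - np.exp(-k * (times - 60))))
        fit = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
        assert fit.converged
        assert fit.amplitude_A == pytest.approx(A, rel=1e-6)
        assert fit.k_obs == pytest.approx(k, rel=1e-6)
        assert fit.rmse < 1e-10 * A
        assert fit.n_points == 80

    def test_scale_equivariance(self):
        times = np.arange(0, 520, 5.5)
        rng = np.random.default_rng(2)
        sig = np.where(times < 60, 0.0, 0.8 * (1 - np.exp(-4e-3 * (times - 60))))
        sig = sig + rng.normal(0, 0.01, sig.size)
        f1 = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
        f2 = m.fit_binding_curve(make_trace(times, 7.3 * sig), t0=60.0)
        assert f2.amplitude_A == pytest.approx(7.3 * f1.amplitude_A, rel=1e-9)
        assert f2.k_obs == pytest.approx(f1.k_obs, rel=1e-9)

    def test_time_shift_covariance(self):
        times = np.arange(0, 520, 5.5)
        rng = np.random.default_rng(3)
        sig = np.where(times < 60, 0.0, 0.8 * (1 - np.exp(-4e-3 * (times - 60))))
        sig = sig + rng.normal(0, 0.01, sig.size)
        f1 = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
        f2 = m.fit_binding_curve(make_trace(times + 33.0, sig), t0=93.0)
        assert f2.k_obs == pytest.approx(f1.k_obs, rel=1e-9)
        assert f2.amplitude_A == pytest.approx(f1.amplitude_A, rel=1e-9)

    def test_flat_noise_trace_yields_no_spurious_rate(self):
        """Non-binder traces: k_obs indistinguishable from 0 or non-converged."""
        times = np.arange(0, 520, 5.5)
        ok = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(seed)
            sig = rng.normal(0, 0.02, times.size)
            fit = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
            amp_null = abs(fit.amplitude_A) < 2 * fit.se_A
            rate_null = abs(fit.k_obs) < 2 * fit.se_kobs
            if (not fit.converged) or rate_null or amp_null:
                ok += 1
        assert ok / n >= 0.90

    def test_jacobian_se_calibrated_against_monte_carlo(self):
        """Empirical k_obs scatter vs reported SE at 2% noise."""
        times = np.arange(0, 520, 5.5)
        clean = np.where(times < 60, 0.0, 0.9 * (1 - np.exp(-5e-3 * (times - 60))))
        ks, ses = [], []
        rng = np.random.default_rng(17)
        for _ in range(300):
            sig = clean + rng.normal(0, 0.02, times.size)
            fit = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
            if fit.converged:
                ks.append(fit.k_obs)
                ses.append(fit.se_kobs)
        emp_sd = np.std(ks, ddof=1)
        assert emp_sd == pytest.approx(np.median(ses), rel=0.25)

    def test_window_truncation_warns(self):
        times = np.arange(0, 200, 5.5)  # only ~25 points after t0
        sig = np.where(times < 60, 0.0, 1 - np.exp(-5e-3 * (times - 60)))
        with pytest.warns(UserWarning, match="truncated"):
            fit = m.fit_binding_curve(make_trace(times, sig), t0=60.0)
        assert fit.window_truncated and fit.n_points < 80

    def test_too_few_points_after_onset_rejected(self):
        times = np.arange(0, 80, 5.5)
        with pytest.raises(WindowingError):
            m.fit_binding_curve(make_trace(times, np.zeros_like(times)), t0=60.0)

    def test_all_nan_trace_rejected(self):
        times = np.arange(0, 520, 5.5)
        sig = np.zeros_like(times)
        tr = make_trace(times, sig)
        est = ExponentialAssociationFitter(t0=60.0)
        with pytest.raises(ValueError, match="NaN"):
            est.fit(times, np.full_like(times, np.nan))
        del tr

    def test_dissociation_phase_unsupported(self):
        with pytest.raises(NotImplementedError):
            dissociation_phase_fit()


class TestAggregateDuplicates:
    def _fit(self, bait, channel, sensor, k, A=1.0):
        return m.ExponentialFit(bait=bait, channel=channel, sensor=sensor,
                                amplitude_A=A, k_obs=k, t0=60.0, se_A=0.01,
                                se_kobs=1e-4, rmse=0.01, n_points=80, converged=True)

    def test_identical_duplicates_sd_zero(self):
        agg = aggregate_duplicates([self._fit("X", 0, 0, 5e-3), self._fit("X", 0, 1, 5e-3)])
        assert agg.k_obs_sd.iloc[0] == 0.0

    def test_hand_computed_mean_and_sd(self):
        agg = aggregate_duplicates([self._fit("X", 0, 0, 2.0), self._fit("X", 0, 1, 4.0)])
        assert agg.k_obs_mean.iloc[0] == pytest.approx(3.0)
        assert agg.k_obs_sd.iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_singleton_sd_missing_not_zero(self):
        agg = aggregate_duplicates([self._fit("X", 0, 0, 5e-3)])
        assert np.isnan(agg.k_obs_sd.iloc[0])

    def test_amplitude_heterogeneity_does_not_scatter_rate(self, layout, batch, truth_map):
        """amp_cv spreads duplicate amplitudes but not duplicate rates."""
        nm = m.NoiseModel(sigma_rel=0.0, amp_cv=0.1, seed=21)
        traces = m.simulate_dataset(layout, batch, truth_map, nm, 520.0)
        traces = m.subtract_reference(traces, layout)
        agg = aggregate_duplicates(fit_all_probes(traces, 60.0))
        binders = agg[agg.bait.isin(["PD-L1", "PD-L2"])]
        assert (binders.amplitude_sd / binders.amplitude_mean).min() > 1e-4
        assert (binders.k_obs_sd / binders.k_obs_mean).max() < 1e-6
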