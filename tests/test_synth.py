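"""Forward simulator: dose-response, frequency map, kernels, noise, scenarios."""

import numpy as np
import pytest

from oectmap import (
    DeviceParams,
    NoiseParams,
    ReleaseEvent,
    Scenario,
    ScenarioConfig,
    StimulusProtocol,
    default_noise_sigma,
    dose_response_amplitude,
    expected_range_factor,
    frequency_response_factor,
    noise_series,
    release_concentration_series,
    synthesize_experiment,
    synthesize_trace,
    synthesize_transfer_sweep,
    transfer_current,
)
from oectmap.errors import InvalidParameterError, ScenarioError


class TestDoseResponse:
    @pytest.mark.parametrize(
        "pulses, expected",
        [(1, 36.13), (100, 356.05), (10, 36.13 + 319.92 * 9 / 99)],
    )
    def test_anchored_linear_interpolation(self, pulses, expected):
        assert dose_response_amplitude(pulses) == pytest.approx(expected, rel=1e-12)

    def test_affine_in_pulse_count(self):
        p = np.array([1, 25, 50, 75, 100], dtype=float)
        amps = np.array([dose_response_amplitude(x) for x in p])
        assert np.allclose(np.diff(amps) / np.diff(p), (356.05 - 36.13) / 99)

    @pytest.mark.parametrize("pulses", [0, 101, -5])
    def test_out_of_range(self, pulses):
        with pytest.raises(InvalidParameterError):
            dose_response_amplitude(pulses)


class TestFrequencyResponse:
    def test_maximal_at_50_hz(self):
        assert frequency_response_factor(50.0) == 1.0
        assert frequency_response_factor(30.0) < 1.0
        assert frequency_response_factor(50.0) > frequency_response_factor(100.0)

    def test_interpolates_between_anchors(self):
        f40 = frequency_response_factor(40.0)
        assert 0.6 < f40 < 1.0

    def test_override_must_keep_50_hz_maximal(self):
        with pytest.raises(InvalidParameterError):
            frequency_response_factor(50.0, {30.0: 1.2, 50.0: 1.0, 100.0: 0.7})
        # a valid override with the right ordering still peaks at 50 Hz
        fac = {30.0: 0.8, 50.0: 1.0, 100.0: 0.9}
        assert frequency_response_factor(50.0, fac) == max(
            frequency_response_factor(f, fac) for f in (30.0, 50.0, 100.0)
        )

    def test_invalid_frequency(self):
        with pytest.raises(InvalidParameterError):
            frequency_response_factor(-10.0)
        with pytest.raises(InvalidParameterError):
            frequency_response_factor(500.0)


class TestReleaseKernel:
    def test_causal_and_normalized(self):
        ev = ReleaseEvent("s", onset=5.0, peak_concentration=120.0)
        t = np.arange(0, 40, 0.001)
        c = release_concentration_series(ev, t)
        assert np.all(c[t < 5.0] == 0.0)
        assert c.max() == pytest.approx(120.0, rel=1e-3)
        assert np.all(c >= 0)

    def test_zero_peak_is_identically_zero(self):
        ev = ReleaseEvent("s", onset=1.0, peak_concentration=0.0)
        assert np.all(release_concentration_series(ev, np.linspace(0, 10, 100)) == 0)

    def test_rise_must_precede_decay(self):
        with pytest.raises(InvalidParameterError):
            ReleaseEvent("s", onset=0.0, peak_concentration=10.0, rise_tau=3.0, decay_tau=2.0)


class TestNoiseModel:
    def test_noiseless_limit(self):
        assert np.all(noise_series(50, sigma=0.0, drift_amplitude=0.0, seed=0) == 0.0)

    def test_determinism(self):
        a = noise_series(200, seed=99)
        b = noise_series(200, seed=99)
        assert np.array_equal(a, b)

    def test_expected_range_factor_against_monte_carlo(self, rng):
        # independent simulation oracle for the quadrature constant
        samples = rng.normal(size=(20000, 20))
        mc = np.ptp(samples, axis=1).mean()
        assert expected_range_factor(20) == pytest.approx(mc, rel=0.01)

    def test_default_sigma_hits_target_peak_to_peak(self):
        # mean 1 s-window (20-sample) peak-to-peak within 5% of 1.16 nA
        sigma = default_noise_sigma(0.05)
        assert sigma == pytest.approx(1.16e-9 / 3.735, rel=1e-3)
        x = noise_series(20 * 2000, dt=0.05, seed=7)
        pp = np.ptp(x.reshape(2000, 20), axis=1)
        assert pp.mean() == pytest.approx(1.16e-9, rel=0.05)

    def test_drift_adds_low_frequency_component(self):
        quiet = noise_series(500, sigma=0.0, drift_amplitude=1e-9, seed=3)
        assert np.ptp(quiet) > 0


class TestSynthesizeTrace:
    def test_null_forward_model_is_flat(self, device):
        tr = synthesize_trace(
            StimulusProtocol(), [], device, noise_params=NoiseParams(sigma=0.0), seed=0
        )
        op_current = transfer_current(device.transfer_v0, device)
        assert np.allclose(tr.i_ds, op_current)
        assert tr.v_gs_operating == device.transfer_v0

    def test_noiseless_minimum_matches_closed_form(self, device):
        ev = ReleaseEvent("s", onset=10.0, peak_concentration=200.0)
        tr = synthesize_trace(
            StimulusProtocol(), [ev], device, (2.0, 0.5), NoiseParams(sigma=0.0), seed=0
        )
        dv = 2.0e-3 * 200.0**0.5
        expected_min = transfer_current(device.transfer_v0 + dv, device)
        # grid sampling of the kernel peak costs a sliver of amplitude
        assert tr.i_ds.min() == pytest.approx(expected_min, rel=1e-3)

    def test_evoked_deflection_is_downward(self, device, rng):
        ev = ReleaseEvent("s", onset=10.0, peak_concentration=50.0)
        tr = synthesize_trace(StimulusProtocol(), [ev], device, seed=rng)
        baseline = tr.i_ds[: int(10 / tr.dt)].mean()
        assert tr.i_ds.min() < baseline

    def test_event_before_protocol_onset_rejected(self, device):
        ev = ReleaseEvent("s", onset=1.0, peak_concentration=50.0)
        with pytest.raises(ScenarioError):
            synthesize_trace(StimulusProtocol(onset_time=10.0), [ev], device)


class TestSynthesizeSweep:
    def test_noiseless_equals_parametric(self, device):
        sw = synthesize_transfer_sweep(device, noise_sigma=0.0, seed=0)
        assert np.allclose(sw.i_ds_values, transfer_current(sw.v_gs_grid, device))

    def test_spans_sweep_range(self, device):
        sw = synthesize_transfer_sweep(device, seed=0)
        assert sw.v_gs_grid[0] == 0.0
        assert sw.v_gs_grid[-1] == pytest.approx(1.2)

    def test_seeded_determinism(self, device):
        a = synthesize_transfer_sweep(device, seed=5)
        b = synthesize_transfer_sweep(device, seed=5)
        assert np.array_equal(a.i_ds_values, b.i_ds_values)

    def test_minimum_points(self, device):
        with pytest.raises(InvalidParameterError):
            synthesize_transfer_sweep(device, n_points=3)


class TestScenarios:
    def test_control_offtarget_has_zero_ground_truth(self):
        cfg = ScenarioConfig(scenario="control_offtarget", seed=2, n_trials=4)
        exp = synthesize_experiment(cfg)
        assert all(t.meta["true_peak_nM"] == 0.0 for t in exp.traces)
        assert all(not t.ground_truth for t in exp.traces)

    def test_bit_identical_under_same_seed(self):
        cfg = dict(scenario="mesolimbic", seed=11, n_trials=2)
        a = synthesize_experiment(ScenarioConfig(**cfg))
        b = synthesize_experiment(ScenarioConfig(**cfg))
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.i_ds, tb.i_ds)
        assert np.array_equal(a.sweep.i_ds_values, b.sweep.i_ds_values)
        assert a.calibration_table.equals(b.calibration_table)

    def test_different_seeds_differ(self):
        a = synthesize_experiment(ScenarioConfig(scenario="mesolimbic", seed=1, n_trials=1))
        b = synthesize_experiment(ScenarioConfig(scenario="mesolimbic", seed=2, n_trials=1))
        assert not np.array_equal(a.traces[0].i_ds, b.traces[0].i_ds)

    def test_mesolimbic_site_heterogeneity(self):
        cfg = ScenarioConfig(scenario="mesolimbic", seed=3, n_trials=3, trial_cv=0.0)
        exp = synthesize_experiment(cfg)
        peaks = {t.site_id: t.meta["true_peak_nM"] for t in exp.traces}
        assert peaks["nac_unit1"] > peaks["nac_unit2"] > 0

    def test_lesion_scenario_cell_structure(self):
        cfg = ScenarioConfig(scenario="lesion", seed=4, n_trials=2, trial_cv=0.0)
        exp = synthesize_experiment(cfg)
        amp = {
            (t.site_id, t.meta["stim_site"], t.meta["condition"]): t.meta["true_peak_nM"]
            for t in exp.traces
        }
        # upper CPu unchanged, NAc under SNc stimulation strongly attenuated
        assert amp[("cpu_upper", "vta", "post")] == amp[("cpu_upper", "vta", "pre")]
        assert amp[("nac", "snc", "post")] == pytest.approx(
            0.3 * amp[("nac", "snc", "pre")]
        )
        assert amp[("cpu_lower", "vta", "post")] < amp[("cpu_lower", "vta", "pre")]

    def test_calibration_table_spans_declared_range(self):
        exp = synthesize_experiment(ScenarioConfig(scenario="mesolimbic", seed=0, n_trials=1))
        c = exp.calibration_table["concentration_nM"]
        assert c.min() == pytest.approx(30.0)
        assert c.max() == pytest.approx(1e5)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="made_up")
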