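"""Physical device model: capacitances, Nernstian/power-law response, transfer curve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oectmap import (
    DeviceParams,
    TransferCurve,
    capacitance_ratio,
    channel_volumetric_capacitance,
    gate_interface_capacitance,
    nernstian_shift,
    optimal_operating_point,
    powerlaw_shift,
    transconductance,
    transfer_current,
)
from oectmap.device import BOLTZMANN_K, ELEMENTARY_CHARGE_Q
from oectmap.errors import (
    CharacterizationError,
    DomainError,
    InvalidParameterError,
)


class TestCapacitances:
    def test_reference_channel_is_0p47_nF(self):
        # 39 F/cm³ over a 40 x 10 x 0.03 µm³ channel
        c = channel_volumetric_capacitance(39.0, 40.0, 10.0, 0.03)
        assert c == pytest.approx(4.68e-10, rel=1e-12)
        assert round(c * 1e9, 2) == 0.47  # 2 significant figures

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((39.0, 0.0, 10.0, 0.03), 0.0),  # zero volume
            ((1.0, 1e4, 1e4, 1e4), 1.0),  # exactly 1 cm³ at 1 F/cm³
        ],
    )
    def test_channel_capacitance_limits(self, args, expected):
        assert channel_volumetric_capacitance(*args) == pytest.approx(expected)

    def test_gate_capacitance_arithmetic(self):
        # 10 µF/cm² double layer over 0.08 x 0.06 cm² -> 48 nF by plain arithmetic
        assert gate_interface_capacitance(10.0, 0.08 * 0.06) == pytest.approx(4.8e-8)
        assert gate_interface_capacitance(10.0, 0.0) == 0.0
        assert gate_interface_capacitance(1.0, 1.0) == pytest.approx(1e-6)

    def test_capacitance_ratio(self):
        assert capacitance_ratio(0.47e-9, 4.8e-9) == pytest.approx(0.0979, abs=2e-4)
        assert capacitance_ratio(0.47e-9, 48e-9) == pytest.approx(0.00979, abs=2e-5)
        assert capacitance_ratio(3.3e-9, 3.3e-9) == 1.0

    @pytest.mark.parametrize(
        "fn, args",
        [
            (channel_volumetric_capacitance, (-1.0, 1, 1, 1)),
            (channel_volumetric_capacitance, (1.0, -1, 1, 1)),
            (gate_interface_capacitance, (-1.0, 1.0)),
            (gate_interface_capacitance, (1.0, -1.0)),
            (capacitance_ratio, (1.0, 0.0)),
            (capacitance_ratio, (-1.0, 1.0)),
        ],
    )
    def test_invalid_arguments_raise(self, fn, args):
        with pytest.raises(InvalidParameterError):
            fn(*args)


class TestNernstianShift:
    def test_per_decade_slope_two_electrons(self):
        # ln(10)·kT/(2q) at 298.15 K, gamma = 0
        expected = math.log(10) * BOLTZMANN_K * 298.15 / (2 * ELEMENTARY_CHARGE_Q)
        assert nernstian_shift(1.0, 0.0, 298.15, 2) == pytest.approx(expected)
        assert nernstian_shift(1.0, 0.0, 298.15, 2) == pytest.approx(29.58e-3, rel=1e-3)

    def test_zero_decades_is_zero(self):
        assert nernstian_shift(0.0, 0.7, 310.0, 2) == 0.0

    def test_linear_in_one_plus_gamma(self):
        base = nernstian_shift(1.0, 0.0, 298.15, 2)
        assert nernstian_shift(1.0, 1.0, 298.15, 2) == pytest.approx(2 * base)
        assert nernstian_shift(1.0, 3.0, 298.15, 2) == pytest.approx(4 * base)

    def test_antisymmetric_in_concentration_ratio(self):
        up = nernstian_shift(2.0, 0.1, 310.0, 2)
        down = nernstian_shift(-2.0, 0.1, 310.0, 2)
        assert up == pytest.approx(-down)

    def test_linear_in_temperature_and_decades(self):
        v1 = nernstian_shift(1.0, 0.2, 300.0, 1)
        assert nernstian_shift(1.0, 0.2, 600.0, 1) == pytest.approx(2 * v1)
        assert nernstian_shift(3.0, 0.2, 300.0, 1) == pytest.approx(3 * v1)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            nernstian_shift(1.0, 0.0, -5.0, 2)
        with pytest.raises(InvalidParameterError):
            nernstian_shift(1.0, 0.0, 298.15, 0)


class TestPowerLawShift:
    def test_direct_evaluation(self):
        # A = 2 mV·nM^-0.5: 100 nM -> 20 mV
        assert powerlaw_shift(100.0, 2e-3, 0.5) == pytest.approx(20e-3)
        assert powerlaw_shift(0.0, 2e-3, 0.5) == 0.0
        # identity exponent: C nM -> C mV numerically
        assert powerlaw_shift(73.0, 1e-3, 1.0) == pytest.approx(73e-3)

    def test_strictly_increasing_and_loglog_affine(self):
        conc = np.geomspace(1, 1e5, 40)
        dv = powerlaw_shift(conc, 2e-3, 0.5)
        assert np.all(np.diff(dv) > 0)
        slope = np.polyfit(np.log(conc), np.log(dv), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_negative_concentration_raises(self):
        with pytest.raises(InvalidParameterError):
            powerlaw_shift(-1.0, 2e-3, 0.5)


class TestTransferCurve:
    def test_sigmoid_midpoint_and_limits(self, bench_device):
        assert transfer_current(0.6, bench_device) == pytest.approx(0.5e-3)
        assert transfer_current(50.0, bench_device) == pytest.approx(0.0, abs=1e-30)
        # exp((V - V0)/s) = 3 -> I = imax/4
        v = 0.6 + 0.15 * math.log(3)
        assert transfer_current(v, bench_device) == pytest.approx(0.25e-3, rel=1e-9)

    def test_strictly_decreasing(self, bench_device):
        v = np.linspace(0, 1.2, 500)
        i = transfer_current(v, bench_device)
        assert np.all(np.diff(i) < 0)

    def test_parametric_transconductance_at_v0(self, bench_device):
        # analytic |dI/dV| at the midpoint is imax/(4s)
        assert transconductance(bench_device, 0.6) == pytest.approx(1e-3 / 0.6, rel=1e-12)

    def test_parametric_gm_matches_finite_difference(self, bench_device):
        h = 1e-4
        for v in np.linspace(0.1, 1.1, 21):
            fd = abs(
                transfer_current(v + h, bench_device) - transfer_current(v - h, bench_device)
            ) / (2 * h)
            assert transconductance(bench_device, v) == pytest.approx(fd, rel=1e-3)

    def test_sampled_gm_near_analytic(self, bench_device):
        v = np.linspace(0.0, 1.2, 201)
        curve = TransferCurve(v, transfer_current(v, bench_device), v_ds=0.06)
        gm = transconductance(curve, 0.6)
        assert gm == pytest.approx(1e-3 / 0.6, rel=1e-2)

    def test_flat_segment_zero_gm(self):
        v = np.linspace(0, 1, 11)
        i = np.concatenate([np.linspace(2e-3, 1e-3, 5), np.full(6, 1e-3)])
        curve = TransferCurve(v, i, v_ds=0.06)
        assert transconductance(curve, 0.95) == pytest.approx(0.0, abs=1e-12)

    def test_gm_outside_domain_raises(self, bench_device):
        v = np.linspace(0.0, 1.2, 50)
        curve = TransferCurve(v, transfer_current(v, bench_device), v_ds=0.06)
        with pytest.raises(DomainError):
            transconductance(curve, 1.5)


class TestOperatingPoint:
    def test_parametric_is_v0(self, bench_device):
        assert optimal_operating_point(bench_device) == 0.6

    def test_sampled_noiseless_sigmoid(self, bench_device):
        v = np.linspace(0.0, 1.2, 241)  # 5 mV grid
        curve = TransferCurve(v, transfer_current(v, bench_device), v_ds=0.06)
        assert abs(optimal_operating_point(curve) - 0.6) <= 0.005 + 1e-12

    def test_injected_gm_peak_location(self):
        # piecewise curve constructed so the finite-difference g_m peaks at 0.65 V
        v = np.linspace(0.0, 1.3, 131)
        i = 1e-3 * (1.0 - 0.5 * (1 + np.tanh((v - 0.65) / 0.1)))
        curve = TransferCurve(v, i, v_ds=0.06)
        assert optimal_operating_point(curve) == pytest.approx(0.65, abs=0.011)

    def test_too_few_samples(self):
        curve = TransferCurve([0, 1, 2], [3e-3, 2e-3, 1e-3], v_ds=0.06)
        with pytest.raises(CharacterizationError):
            optimal_operating_point(curve)

    def test_non_decreasing_curve_rejected(self):
        v = np.linspace(0, 1, 20)
        curve = TransferCurve(v, np.linspace(1e-3, 2e-3, 20), v_ds=0.06)
        with pytest.raises(CharacterizationError):
            optimal_operating_point(curve)

    @settings(deadline=None, max_examples=30)
    @given(
        imax=st.floats(1e-7, 1e-2),
        v0=st.floats(0.3, 0.9),
        s=st.floats(0.05, 0.3),
    )
    def test_sampled_argmax_tracks_v0(self, imax, v0, s):
        dev = DeviceParams(transfer_imax=imax, transfer_v0=v0, transfer_slope_s=s)
        v = np.linspace(0.0, 1.2, 481)
        curve = TransferCurve(v, transfer_current(v, dev), v_ds=0.06)
        assert abs(optimal_operating_point(curve) - v0) <= (v[1] - v[0]) + 1e-12


class TestDeviceParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"channel_width": -1.0},
            {"temperature_T": 0.0},
            {"electrons_transferred_n": 0},
            {"transfer_slope_s": 0.0},
            {"v_ds": -0.06},
        ],
    )
    def test_invalid_fields_raise(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DeviceParams(**kwargs)

    def test_capacitance_summary_gamma(self, device):
        summary = device.capacitance_summary()
        assert summary.c_volumetric == pytest.approx(4.68e-10)
        assert summary.c_gate_electrolyte == pytest.approx(4.8e-8)
        assert summary.gamma == pytest.approx(4.68e-10 / 4.8e-8)
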