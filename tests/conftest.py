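import numpy as np
import pytest

from oectmap import CalibrationFit, DeviceParams, SigmoidTransferModel


@pytest.fixture
def device() -> DeviceParams:
    return DeviceParams()


@pytest.fixture
def bench_device() -> DeviceParams:
    """A milliamp-scale bench device (convenient round numbers)."""
    return DeviceParams(transfer_imax=1e-3, transfer_v0=0.6, transfer_slope_s=0.15)


@pytest.fixture
def bench_model(bench_device) -> SigmoidTransferModel:
    return SigmoidTransferModel(
        bench_device.transfer_imax,
        bench_device.transfer_v0,
        bench_device.transfer_slope_s,
    )


@pytest.fixture
def truth_fit() -> CalibrationFit:
    """The default ground-truth power-law calibration: 2 mV·nM^-0.5."""
    return CalibrationFit(a_mv=2.0, beta=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
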