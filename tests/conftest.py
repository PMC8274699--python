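import numpy as np
import pytest

from cinegate import (AmplifierModel, ECGGateConfig, PhysioParams,
                      RespGateConfig, ScalerConfig, ScanParams,
                      apply_amplifier, scale_voltage, simulate_cardiac,
                      simulate_respiration)


@pytest.fixture(scope="session")
def physio_params():
    return PhysioParams()


@pytest.fixture(scope="session")
def clean_cardiac(physio_params):
    """~40 beats of drift-free, noise-free ECG with ground truth."""
    p = PhysioParams(baseline_drift_amplitude=0.0)
    return simulate_cardiac(p, 134.0 * 42, seed=11)


@pytest.fixture(scope="session")
def clean_respiration():
    """~30 breaths of drift-free respiration with ground truth."""
    p = PhysioParams(baseline_drift_amplitude=0.0)
    return simulate_respiration(p, 30_000.0, seed=12)


@pytest.fixture(scope="session")
def scaled_clean_ecg(clean_cardiac):
    """Clean cardiac trace through the default ECG front end."""
    trace, truth = clean_cardiac
    amp = apply_amplifier(trace, AmplifierModel.ecg_default())
    scaled, _ = scale_voltage(amp, ScalerConfig())
    return scaled, truth


@pytest.fixture
def resp_cfg():
    return RespGateConfig()


@pytest.fixture
def ecg_cfg():
    return ECGGateConfig()


@pytest.fixture
def scan_params():
    return ScanParams()
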