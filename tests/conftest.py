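import dataclasses

import numpy as np
import pytest

import pelvimon as pm
from pelvimon.config import RunConfig


@pytest.fixture(scope="session")
def wide_adc_config() -> pm.ChainConfig:
    """Chain config with a wide ADC range so closed-form bench levels
    (13.75 V for a 2.5 V carrier) are not clipped."""
    return dataclasses.replace(pm.ChainConfig(), adc_range_v=20.0)


@pytest.fixture(scope="session")
def reference_result() -> pm.PipelineResult:
    """One full reference run (3 x 30 s stim / 120 s rest at 20 kHz raw),
    shared across tests; the raw recording is kept for re-demodulation."""
    cfg = dataclasses.replace(
        RunConfig(),
        seed=1,
        analysis=dataclasses.replace(RunConfig().analysis, store_raw=True),
    )
    return pm.run_pipeline(cfg)


@pytest.fixture(scope="session")
def short_rest_result() -> pm.PipelineResult:
    """Reference protocol with rests shortened to 30 s (incomplete relaxation)."""
    base = RunConfig()
    cfg = dataclasses.replace(
        base,
        seed=7,
        protocol=dataclasses.replace(base.protocol, rest_s=30.0),
    )
    return pm.run_pipeline(cfg)


@pytest.fixture()
def steady_impedance():
    """A constant-impedance trace factory on a 100 Hz control grid."""

    def make(z: complex, duration_s: float = 3.0) -> pm.TissueImpedanceTrace:
        t = np.arange(0.0, duration_s, 0.01)
        return pm.TissueImpedanceTrace(t, np.full(len(t), z, dtype=complex))

    return make
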