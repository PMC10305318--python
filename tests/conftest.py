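import numpy as np
import pytest

from fallsense import PipelineConfig, SensorLog
from fallsense.config import STANDARD_PRESSURE_PA


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_still_log(duration_s: float = 10.0, rate_hz: float = 100.0,
                   pressure_pa: float = STANDARD_PRESSURE_PA) -> SensorLog:
    """Perfectly quiet upright trace: 1 g on +Y (superior axis), constant pressure."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    acc = np.tile([0.0, 1.0, 0.0], (n, 1))
    gyro = np.zeros((n, 3))
    pressure = np.full(n, pressure_pa)
    return SensorLog(t=t, acc=acc, gyro=gyro, pressure=pressure, rate_hz=rate_hz)


@pytest.fixture
def still_log() -> SensorLog:
    return make_still_log()
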