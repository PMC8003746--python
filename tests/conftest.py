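import numpy as np
import pytest

from nanotherm.photothermal import SampleThermalSpec
from nanotherm.synthetic import (
    LumpedModelParams,
    generate_photothermal_trace,
    paper_operating_point,
    water_control_params,
)

# schedule long enough for the lumped model to reach its plateau (tau ~221 s)
PLATEAU_SCHEDULE = ((1800.0, True), (2400.0, False))


@pytest.fixture(scope="session")
def operating_point() -> LumpedModelParams:
    return paper_operating_point()


@pytest.fixture(scope="session")
def sample_spec(operating_point) -> SampleThermalSpec:
    return operating_point.sample_spec()


@pytest.fixture(scope="session")
def plateau_trace(operating_point):
    """Noise-free suspension trace irradiated to steady state."""
    return generate_photothermal_trace(operating_point, PLATEAU_SCHEDULE, dt=1.0)


@pytest.fixture(scope="session")
def water_trace(operating_point):
    """Matching water-only control trace."""
    return generate_photothermal_trace(
        water_control_params(operating_point), PLATEAU_SCHEDULE, dt=1.0
    )
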