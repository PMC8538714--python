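import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from voridial import PopulationParameters, RRTSettings
from voridial.cohort import StudyDesign


@pytest.fixture(scope="session")
def params() -> PopulationParameters:
    return PopulationParameters()


@pytest.fixture(scope="session")
def rrt() -> RRTSettings:
    return RRTSettings()


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def low_ruv_params(params) -> PopulationParameters:
    """Default typical values with a 5% residual CV on every stream."""
    return params.with_(ruv_prop={"pre": 5.0, "post": 5.0, "effluent": 5.0})


@pytest.fixture(scope="session")
def rich_design() -> StudyDesign:
    """Hourly three-stream sampling over the 49 h study window."""
    return StudyDesign(sampling_times=tuple(np.arange(0.0, 49.5, 1.0)))
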