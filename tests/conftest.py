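import numpy as np
import pytest

from myocyte import build_parameters
from myocyte.snapshots import steady_state


@pytest.fixture(scope="session")
def male():
    return build_parameters("male")


@pytest.fixture(scope="session")
def female():
    return build_parameters("female")


@pytest.fixture(scope="session")
def y_male():
    """Converged 1 Hz end-diastolic state for the male preset."""
    return steady_state("male", 1.0)


@pytest.fixture(scope="session")
def beat_male(male, y_male):
    """One recorded steady-state beat at 1 Hz (0.25 ms sampling)."""
    from myocyte import pace, SolverSettings
    return pace(male, 1000.0, 3, y0=y_male, record_from=2,
                settings=SolverSettings(dt_sample=0.25))
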