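import numpy as np
import pytest
from hypothesis import settings

from compchip import InductionCurve, build_bias_table
from compchip.series import DEFAULT_TIME_GRID

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def induction():
    """The fitted TBP competitor induction curve (saturation 2.23, 22 min)."""
    return InductionCurve(rho_inf=2.23, t_ind=22.0, hill_n=4)


@pytest.fixture(scope="session")
def time_grid():
    return np.asarray(DEFAULT_TIME_GRID)


@pytest.fixture(scope="session")
def bias_table(induction, time_grid):
    """Shared lookup table for the default induction curve and time grid."""
    return build_bias_table(induction, times=time_grid)
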