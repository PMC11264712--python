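import numpy as np
import pytest

from vbseq import DesignParams, PriorSpec
from vbseq.boundary_solver import DPConfig, solve_boundary


@pytest.fixture(scope="session")
def params() -> DesignParams:
    """Main-analysis design constants (T_max = 124, tau = 74)."""
    return DesignParams()


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def boundary124(params, prior):
    """Stopping boundary for the main analysis, with value surface kept."""
    return solve_boundary(params, prior, DPConfig(),
                          store_value_surface=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
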