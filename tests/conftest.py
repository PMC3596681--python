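import numpy as np
import pytest

from gttfit import (
    CASE1_PARAMS,
    CASE2_PARAMS,
    IntegratorConfig,
    ObjectiveConfig,
    SynthConfig,
    simulate_gtt,
    table1_fixture,
)


@pytest.fixture
def case1_params():
    return CASE1_PARAMS


@pytest.fixture
def case2_params():
    return CASE2_PARAMS


@pytest.fixture
def table1():
    """(case 1, case 2) measured GTT deviation series."""
    return table1_fixture()


@pytest.fixture
def fast_objective_config():
    """Objective with a 1-min RK4 step: discretisation error ~1e-10 on these
    dynamics, an order of magnitude below anything asserted, at a fraction
    of the default step's cost."""
    return ObjectiveConfig(integrator=IntegratorConfig(step=1.0))


@pytest.fixture
def noise_free_case1():
    """Noise-free synthetic series drawn from the case-1 parameters at the
    standard hourly sample times."""
    return simulate_gtt(SynthConfig(params=CASE1_PARAMS))


def expm_trajectory(params, times, y0=(80.0, 0.0)):
    """Independent linear-systems oracle: state via scipy's matrix exponential."""
    from scipy.linalg import expm

    A = np.array([[-params.p1, -params.p2], [params.p3, -params.p4]])
    return np.array([expm(A * t) @ np.asarray(y0, dtype=float) for t in np.asarray(times)])
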