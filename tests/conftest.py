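import numpy as np
import pytest

from israpop import default_params, equilibrate
from israpop.solver import SolverConfig


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def steady(params):
    return equilibrate(params)


@pytest.fixture(scope="session")
def steady_state(steady):
    return steady.state


@pytest.fixture(scope="session")
def fast_solver():
    """Solver settings for tests that only need qualitative accuracy."""
    return SolverConfig(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def coarse_points():
    return 600


@pytest.fixture(scope="session")
def condition_trajectories(params, steady_state, fast_solver, coarse_points):
    """The four study conditions simulated once per session."""
    from israpop.protocols import run_protocol
    return {name: run_protocol(params, name, solver_cfg=fast_solver,
                               steady_state=steady_state,
                               output_points=coarse_points)
            for name in ("untreated", "ven_mono", "ted_mono", "combo")}
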