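import pytest

from pdukinetics.calibrate import calibrate
from pdukinetics.params import default_parameters
from pdukinetics.simulate import run_simulation
from pdukinetics.synth import GrowthModel, generate_growth_curve


@pytest.fixture(scope="session")
def growth():
    """Synthetic wild-type growth curve (biphasic, doubling 3.17 h then 9.2 h)."""
    return generate_growth_curve(GrowthModel())


@pytest.fixture(scope="session")
def base_params():
    """The shipped calibrated base case: 15 spherical MCPs, 140 nm."""
    return default_parameters()


@pytest.fixture(scope="session")
def base_result(base_params, growth):
    """Forward simulation of the base case over the 30 h horizon."""
    return run_simulation(base_params, growth)


@pytest.fixture(scope="session")
def calibration(base_params, growth):
    """Full two-stage calibration of {k_c, vmax_P, vmax_Q}; shared because
    the grid search is the most expensive computation in the suite."""
    return calibrate(base_params, growth)
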