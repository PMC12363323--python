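import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nasodose as nd
from nasodose.spray_transport import SprayInjection, deposition_curve

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: droplets per cluster used by simulation-backed tests (desk-scale runs;
#: full-scale clusters use 3,000 droplets)
TEST_N_DROPLETS = 400


@pytest.fixture(scope="session")
def model():
    return nd.build_idealized_airway()


@pytest.fixture(scope="session")
def flow15():
    return nd.FlowField(rate_lpm=15.0)


@pytest.fixture(scope="session")
def flow30():
    return nd.FlowField(rate_lpm=30.0)


@pytest.fixture(scope="session")
def constants():
    return nd.PhysicalConstants()


@pytest.fixture(scope="session")
def iu(model):
    return nd.iu_axis(model)


@pytest.fixture(scope="session")
def cu(model):
    return nd.cu_axis(model)


@pytest.fixture(scope="session")
def template():
    return SprayInjection(
        origin=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]), n_droplets=TEST_N_DROPLETS
    )


@pytest.fixture(scope="session")
def sim_curves(model, flow15, flow30, iu, cu, template):
    """IU and CU deposition curves at both inhalation rates (shared)."""
    out = {}
    for flow in (flow15, flow30):
        for axis in (iu, cu):
            out[(axis.protocol, flow.rate_lpm)] = deposition_curve(
                axis, model, flow, template, seed=42
            )
    return out
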