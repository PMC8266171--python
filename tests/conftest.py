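import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coarse_annulus():
    from atherofem.geometry import make_annulus_mesh
    from atherofem.params import GeometryParams

    return make_annulus_mesh(GeometryParams(mesh_size=2.5))


@pytest.fixture(scope="session")
def canned_runs():
    """The three canonical 2D disease scenarios, run once per session."""
    from atherofem.fem_solver import Simulation
    from atherofem.fixtures import canned_case

    out = {}
    for name in ("no_fiber_no_vv", "fiber_no_vv", "fiber_vv"):
        sim = Simulation(canned_case(name))
        out[name] = (sim, sim.run())
    return out
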