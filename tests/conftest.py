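import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tubelaw as tl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_material():
    """Lung-conduit-like elastic constants: E = 1 MPa, nu = 0.49."""
    return tl.Material(E=1e6, nu=0.49, rho=1000.0)


@pytest.fixture(scope="session")
def reference_geometry():
    """Base triplet shared by the default sweeps: d=3, gamma=0.06, l=1.1."""
    return tl.TubeGeometry(d=3.0, gamma=0.06, l=1.1, r=0.005)


@pytest.fixture(scope="session")
def noiseless_curve():
    """One synthetic tube law with zero noise, reference geometry."""
    return tl.generate_tubelaw(tl.default_generator_config(seed=0, sigma_a=0.0))


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_curve):
    """Buckling-point estimate on the noiseless reference curve."""
    return tl.estimate_from_curve(noiseless_curve)


@pytest.fixture(scope="session")
def l_sweep_knees(reference_material):
    """Explicit l-sweep knee pressures from the general non-dimensional
    constant inverted at the base (d=3, gamma=0.06)."""
    mat = reference_material
    return np.array(
        [
            tl.GENERAL_P_HAT_CRIT * mat.E / (1 - mat.nu**2) * lv**2 * 0.06 / 3.0
            for lv in tl.DEFAULT_SWEEPS["l"]
        ]
    )
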