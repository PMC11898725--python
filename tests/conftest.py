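import numpy as np
import pytest

from napacool import BoundaryConditions, SphereGeometry
from napacool.thermophysics import ConstantProperties, ThermalProperties


@pytest.fixture(scope="session")
def class2_props():
    return ThermalProperties(class_id=2)


@pytest.fixture(scope="session")
def class2_geom():
    return SphereGeometry.for_class(2)


@pytest.fixture(scope="session")
def class2_constant_props(class2_props):
    """Constant-coefficient version of the class-2 properties, evaluated at
    the storage setpoint, for comparison with the analytic series."""
    return ConstantProperties(
        k_const=float(class2_props.k_eff(4.1)),
        rho_cp_const=float(class2_props.rho_cp_eff(4.1)),
    )


@pytest.fixture
def storage_bc():
    return BoundaryConditions(h=270.0, T_inf=4.1, T0=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
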