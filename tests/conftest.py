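import numpy as np
import pytest

from mabrsim import (
    BiofilmGeometry,
    BulkLiquidState,
    KineticParameterSet,
    MembraneBoundary,
    SolverOptions,
    TemperatureRuleSet,
)


@pytest.fixture(scope="session")
def kin():
    """Package default (calibrated) kinetic parameter set."""
    return KineticParameterSet()


@pytest.fixture(scope="session")
def rules():
    """Package default temperature rules."""
    return TemperatureRuleSet()


@pytest.fixture(scope="session")
def options():
    """Production solver settings (100 nodes)."""
    return SolverOptions()


@pytest.fixture(scope="session")
def coarse_options():
    """Cheaper solver settings for property tests that do not probe
    discretisation accuracy."""
    return SolverOptions(n_nodes=50)


@pytest.fixture()
def planar_geom():
    return BiofilmGeometry(mode="planar", Lf=100e-6, L_LBL=50e-6)


@pytest.fixture()
def bulk35():
    return BulkLiquidState(S_bulk=np.array([0.0, 35.0, 0.0, 0.0]), temperature=20.0)


@pytest.fixture()
def membrane():
    return MembraneBoundary()
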