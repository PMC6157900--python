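import numpy as np
import pytest

from pulsewave.arterial_tree import (
    ArterialTree,
    Vessel,
    WindkesselElements,
    nominal_tree,
)
from pulsewave.hemodynamics import (
    NumericsConfig,
    PatientParameters,
    converge_to_periodic,
)

# printed HD cohort means used as the canonical virtual subject
HD_MEAN_KW = dict(
    k1=2.28e7, k3=14.51e5, CO=3.56, tau=101.08, S_R=1.34, S_C=13.57,
)


@pytest.fixture(scope="session")
def tree():
    return nominal_tree()


@pytest.fixture(scope="session")
def hd_mean_params():
    return PatientParameters(**HD_MEAN_KW, HR=70, height=170,
                             brachial_SP=120, brachial_DP=80)


@pytest.fixture(scope="session")
def coarse_numerics():
    return NumericsConfig(dx_cm=1.0)


@pytest.fixture(scope="session")
def hd_mean_sim(tree, hd_mean_params, coarse_numerics):
    """One converged cycle on the nominal tree, shared across tests."""
    cfg = NumericsConfig(dx_cm=1.0, output_dt_ms=0.5)
    return converge_to_periodic(tree, hd_mean_params, config=cfg)


def uniform_tube(length=100.0, radius=0.5, R1=1000.0, R2=4000.0, C=1e-4,
                 p_out=5.0, sites=None) -> ArterialTree:
    """Single uniform vessel with a Windkessel outlet (analytic test bed)."""
    v = Vessel(id=1, name="tube", length=length, r_in=radius, r_out=radius,
               windkessel=WindkesselElements(R1=R1, R2=R2, C=C))
    return ArterialTree(vessels={1: v}, root=1, named_sites=sites or {},
                        p_out=p_out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
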