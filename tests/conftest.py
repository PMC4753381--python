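import numpy as np
import pytest
from hypothesis import settings

import microreactor as mr
from microreactor import fem
from microreactor import geometry as geo

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

#: bead surface resolved with 16 segments -- the coarse test fixture scale
COARSE_BEAD_RES = np.pi * 1e-5 / 16


@pytest.fixture(scope="session")
def hs_params():
    return mr.load_parameters("HsHK2")


@pytest.fixture(scope="session")
def sc_params():
    return mr.load_parameters("ScHK2")


@pytest.fixture(scope="session")
def coarse_bead_mesh():
    """Small 1-bead chamber used by most solver tests (~260 cells)."""
    spec = geo.ChamberSpec(L=500e-6, n_b=1)
    return geo.build_chamber_mesh(spec, resolution=120e-6,
                                  bead_resolution=COARSE_BEAD_RES, grading=0.5)


@pytest.fixture(scope="session")
def default_bead_mesh():
    """1-bead chamber at the default bead resolution (d/8)."""
    spec = geo.ChamberSpec(L=500e-6, n_b=1)
    return geo.build_chamber_mesh(spec, resolution=60e-6)


def make_se_simulator(mesh, params, lam, T=60.0, dt=1.0, D=1e-9,
                      theta_e=0.15, **kw):
    kinetics = mr.SEKinetics(params, lam)
    transport = fem.TransportParameters(D=np.full(5, D), theta_e=theta_e)
    tstep = fem.TimeSteppingConfig(T=T, dt=dt)
    return fem.ReactorSimulator(mesh, kinetics, transport, tstep, **kw)
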