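import numpy as np
import pytest

import acifit as af
from acifit.synthetic import MAIZE_SCHEDULE, SOYBEAN_SCHEDULE, TOBACCO_SCHEDULE

# hand-checkable C3 parameter set used across the model tests
DERIVED_C3 = dict(Vcmax=100.0, J=160.0, Tp=12.0, RL=1.0,
                  Gamma_star=40.0, Kc=270.0, Ko=165.0, O=210.0)

# study conditions: a C3 leaf whose 17-point tobacco-protocol curve has
# Rubisco-, RuBP-regeneration- and TPU-limited segments
C3_BINDING_TRUTH = dict(Vcmax=150.0, J=200.0, Tp=12.0, RL=1.5, alpha_old=0.5)

# same leaf but with electron transport far above every other rate, so
# no point is RuBP-regeneration-limited
C3_J_NONBINDING_TRUTH = dict(Vcmax=150.0, J=400.0, Tp=12.0, RL=1.5, alpha_old=0.5)

VJ_TRUTH = dict(Vcmax=140.0, J=210.0, Tp=13.0, RL=1.2,
                alpha_old=0.4, gmc=0.4, tau=0.426)

C4_TRUTH = dict(Vcmax=65.0, Vpmax=140.0, RL=1.8)


@pytest.fixture
def c3p():
    return af.C3Params(**DERIVED_C3)


def make_curve(model, truth, schedule, noise_sd=0.0, seed=0, replicate=0, **kw):
    spec = af.SimSpec(model=model, true_params=truth, schedule=schedule,
                      noise_sd=noise_sd, seed=seed, **kw)
    table, _ = af.generate_curve(spec, replicate)
    return af.organize_response_curve_data(table, schedule)


@pytest.fixture(scope="session")
def c3_binding_curve():
    return make_curve("c3_aci", C3_BINDING_TRUTH, TOBACCO_SCHEDULE)


@pytest.fixture(scope="session")
def c3_binding_fit(c3_binding_curve):
    return af.fit_curve(c3_binding_curve, "c3_aci")


@pytest.fixture(scope="session")
def vj_curve():
    return make_curve("c3_variable_j", VJ_TRUTH, SOYBEAN_SCHEDULE, qin=2000.0)


@pytest.fixture(scope="session")
def c4_curve():
    return make_curve("c4_aci", C4_TRUTH, MAIZE_SCHEDULE, tleaf=31.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
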