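import numpy as np
import pytest

import tmdd_rebound as tr


@pytest.fixture(scope="session")
def omalizumab_cfg():
    return tr.omalizumab()


@pytest.fixture(scope="session")
def omalizumab_params(omalizumab_cfg):
    return omalizumab_cfg.build_params()


@pytest.fixture(scope="session")
def omalizumab_q(omalizumab_params):
    return tr.nondimensionalize(omalizumab_params)


@pytest.fixture(scope="session")
def omalizumab_h(omalizumab_cfg):
    # mainly-linear feedback with dimensional slope H0 = 1/nM,
    # i.e. dimensionless h0 = R0*H0 = 2.688
    return omalizumab_cfg.build_feedback()


@pytest.fixture(scope="session")
def psoriasis_params():
    return tr.psoriasis().build_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
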