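import numpy as np
import pytest

from twistslide.dynamics import IntegratorConfig
from twistslide.model import ChemicalState, RemodelerParams, SequenceProfile, effective_params
from twistslide.sequences import build_sequence, profile_from_sequence


@pytest.fixture(scope="session")
def base_params():
    return RemodelerParams()


@pytest.fixture(scope="session")
def polyapg_profile():
    return profile_from_sequence(build_sequence("polyApG"))


@pytest.fixture(scope="session")
def atp_params(base_params, polyapg_profile):
    return effective_params(base_params, polyapg_profile, ChemicalState.ATP)


@pytest.fixture(scope="session")
def apo_params(base_params, polyapg_profile):
    return effective_params(base_params, polyapg_profile, ChemicalState.APO)


@pytest.fixture(scope="session")
def uniform_profile():
    # uniform, untilted profile used by symmetry checks
    return SequenceProfile.uniform()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_cfg():
    return IntegratorConfig()
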