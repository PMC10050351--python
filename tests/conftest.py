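import pytest

from fercbci.paradigm import CharacterGrid
from fercbci.preprocess import preprocess_session
from fercbci.synth import SubjectProfile, simulate_calibration
from fercbci import p300 as p300_mod
from fercbci import ssvep as ssvep_mod


@pytest.fixture(scope="session")
def grid():
    return CharacterGrid()


@pytest.fixture(scope="session")
def noiseless_profile():
    return SubjectProfile(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_profile):
    return simulate_calibration(noiseless_profile)


@pytest.fixture(scope="session")
def noiseless_preprocessed(noiseless_calibration):
    return preprocess_session(noiseless_calibration)


@pytest.fixture(scope="session")
def noiseless_p300_model(noiseless_calibration, noiseless_preprocessed):
    return p300_mod.train_ensemble(noiseless_calibration, seed=3,
                                   preprocessed=noiseless_preprocessed)


@pytest.fixture(scope="session")
def noiseless_trca_model(noiseless_preprocessed):
    views = ssvep_mod.target_views_by_line(noiseless_preprocessed)
    return ssvep_mod.fit_trca(views)
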