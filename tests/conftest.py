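import numpy as np
import pytest

from mwdebye.mwdist import MWParameters, SpeciesComponent
from mwdebye.synthdata import default_blood_model

#: Published whole-blood beta-relaxation fit values, reused across the suite.
BLOOD = {
    "delta_eps": 8.993e3,
    "ts": 1.139e-7,
    "tau_c": 2.434e-8,
    "sigma_dc": 3.204e-1,
    "legacy_delta_eps": 1.533e11,
}


@pytest.fixture
def blood_params() -> MWParameters:
    return MWParameters.from_spectroscopy(ts=BLOOD["ts"], tau_c=BLOOD["tau_c"])


@pytest.fixture
def blood_component(blood_params) -> SpeciesComponent:
    return SpeciesComponent(params=blood_params, weight=1.0, label="RBC")


@pytest.fixture
def blood_model():
    return default_blood_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_mw_params(rng: np.random.Generator) -> MWParameters:
    """Randomised but well-scaled Modified-Weibull parameters for property tests."""
    eta = 10.0 ** rng.uniform(-8.0, -6.0)
    gamma = rng.uniform(-1.0, 3.0) * eta
    return MWParameters(eta=eta, gamma=gamma)
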