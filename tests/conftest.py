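import numpy as np
import pytest

from mlmm_power import (
    EffectSpec,
    PopulationParams,
    TrialDesign,
    load_default_config,
)


@pytest.fixture(scope="session")
def mci():
    """Packaged MCI reference configuration: (params, effect, 2-year design)."""
    return load_default_config()


@pytest.fixture(scope="session")
def mci_params(mci):
    return mci[0]


@pytest.fixture(scope="session")
def mci_effect(mci):
    return mci[1]


@pytest.fixture(scope="session")
def design2y(mci):
    return mci[2]


@pytest.fixture(scope="session")
def design6y(mci):
    return mci[2].with_duration(6)


@pytest.fixture(scope="session")
def uni_params():
    """Univariate random-intercept population for J = 1 checks."""
    return PopulationParams(
        beta2=[0.08], sigma_b=[[0.6]], sigma_eps=[[0.5]], beta0=[1.0], labels=("y",)
    )


@pytest.fixture(scope="session")
def toy_iid_params():
    """J = 1, unit error variance, no random intercept (hand-computable)."""
    return PopulationParams(beta2=[0.0], sigma_b=[[0.0]], sigma_eps=[[1.0]])
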