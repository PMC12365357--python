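import numpy as np
import pytest

from melscure.model import Parameters, RandomEffects, Subject


@pytest.fixture(scope="session")
def params_I() -> Parameters:
    """Scenario I generating truth (reference variant)."""
    return Parameters(theta1=1.5, theta2=2.7, theta3=1.9, sigma=0.25,
                      lam=-14.5, phi=4.0, alpha1=-0.6, nu=0.8472978603872034,
                      Sigma=np.diag([0.02, 0.08, 0.17]))


@pytest.fixture(scope="session")
def params_II() -> Parameters:
    """Scenario II generating truth (MELS variant)."""
    return Parameters(theta1=1.5, theta2=2.7, theta3=1.9, theta4=-2.0,
                      lam=-14.7, phi=3.9, alpha1=-0.4, alpha2=3.1,
                      nu=0.8472978603872034,
                      Sigma=np.diag([0.02, 0.07, 0.1, 0.6]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_subjects() -> list[Subject]:
    """One interval-censored and one right-censored subject."""
    return [
        Subject(id="a", times=np.array([12.0, 25.0, 33.0]),
                y=np.array([1.1, 2.9, 3.6]), censoring="interval",
                t_left=33.0, t_right=43.0),
        Subject(id="b", times=np.array([15.0, 40.0]),
                y=np.array([1.8, 4.0]), censoring="right", t_cens=40.0),
    ]
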