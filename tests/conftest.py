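import numpy as np
import pytest

from phenofluct import FitnessModel, NutrientSignal, default_population_pair


@pytest.fixture(scope="session")
def model():
    """Canonical fitness model: gamma = zeta = 100, d = 0.01."""
    return FitnessModel(gamma=100.0, d=0.01)


@pytest.fixture(scope="session")
def pair():
    """Canonical (H, L) pair: beta_H = 0.025, beta_L = 0.01, shared Gaussian start."""
    return default_population_pair()


@pytest.fixture(scope="session")
def constant_signal():
    return NutrientSignal("constant", M=1.0)


@pytest.fixture(scope="session")
def low_variability_signal():
    return NutrientSignal("sinusoidal", M=1.0, A=0.5, T=5.0)


@pytest.fixture(scope="session")
def high_variability_signal():
    return NutrientSignal("sinusoidal", M=1.0, A=1.0, T=5.0)


@pytest.fixture(scope="session")
def signals(constant_signal, low_variability_signal, high_variability_signal):
    return {"constant": constant_signal,
            "low": low_variability_signal,
            "high": high_variability_signal}
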