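from fractions import Fraction

import pytest
from hypothesis import settings

import operanteq as oq

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def example1():
    return oq.preset_model("example1", {})


@pytest.fixture(scope="session")
def example2():
    return oq.preset_model("example2", {})


@pytest.fixture(scope="session")
def example1_trace(example1):
    """Three exact Picard steps from Γ0(x) = x for the two-choice model."""
    return oq.picard_iterates(example1, n=3)


@pytest.fixture(scope="session")
def martingale_model():
    """Equal-rate model: the state is a martingale and f(x) = x exactly."""
    return oq.preset_model("lyubich_shapiro", {"a1": Fraction(3, 10)})


@pytest.fixture(scope="session")
def asymmetric_model():
    return oq.preset_model(
        "lyubich_shapiro", {"a1": Fraction(3, 10), "a2": Fraction(6, 10)}
    )
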