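import numpy as np
import pytest

from ossein import AgeDensity, generate_fixture


@pytest.fixture
def uniform_c0() -> AgeDensity:
    """Uniform density 1 on [0, 10] with maturity threshold 3."""
    return generate_fixture("collagen", "uniform", {"lo": 0.0, "hi": 10.0, "K": 10.0}, alpha=3.0)


@pytest.fixture
def two_mass_c0() -> AgeDensity:
    """Mixture with 80% of the population already mature (F(0) = 0.8)."""
    return generate_fixture("collagen", "two_mass", {"p_mature": 0.8, "K": 1.0}, alpha=3.0)


@pytest.fixture
def exp_m0():
    """Exponential size density with unit count and unit mean size."""
    return generate_fixture("mineral", "exponential", {"scale": 1.0, "M0": 1.0})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
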