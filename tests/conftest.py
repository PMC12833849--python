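import numpy as np
import pytest

from thzhyd import (
    SolutionComposition,
    default_grid,
    gen_spectrum,
    water_params,
)


@pytest.fixture(scope="session")
def water():
    """Pure-water model parameters at 20 degC (c = 1)."""
    return water_params()


@pytest.fixture(scope="session")
def water_spectrum(water):
    """Noiseless pure-water eps'' spectrum on the 45-point reliable band."""
    return gen_spectrum(water, noise_sd=0.0, label="water")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def sucrose_composition():
    """0.75 mol/L sucrose at an assumed density of 1.100 g/mL."""
    return SolutionComposition(molarity=0.75, density=1.100,
                               molar_mass_osmolyte=342.30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
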