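import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amidefit import load_preset, make_spectrum
from amidefit.synthetic import SpectrumNoiseModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")

# published amide I deconvolution reference values: class -> area percent
FREE_COMPOSITION = {
    "inter-beta-sheet": 7.0,
    "beta-sheet": 58.0,
    "alpha-helix": 25.0,
    "turn": 10.0,
}
ADSORBED_COMPOSITION = {
    "inter-beta-sheet": 5.0,
    "beta-sheet": 42.0,
    "random": 17.0,
    "alpha-helix": 27.0,
    "turn": 9.0,
}


@pytest.fixture(scope="session")
def free_preset():
    return load_preset("free_d2o")


@pytest.fixture(scope="session")
def adsorbed_preset():
    return load_preset("adsorbed_d2o")


@pytest.fixture()
def free_spectrum(free_preset):
    """Noiseless free-state spectrum with a flat-baseline window."""
    return make_spectrum(free_preset, grid_hi=2050.0)


@pytest.fixture()
def adsorbed_spectrum(adsorbed_preset):
    return make_spectrum(adsorbed_preset, grid_hi=2050.0)


@pytest.fixture()
def noisy_free_spectrum(free_preset):
    return make_spectrum(
        free_preset,
        grid_hi=2050.0,
        noise=SpectrumNoiseModel(additive_sigma=0.002, seed=42),
    )


def gaussian(grid, center, fwhm, amplitude):
    """Reference Gaussian used as an independent check in several tests."""
    return amplitude * np.exp(-4.0 * np.log(2.0) * (grid - center) ** 2 / fwhm**2)
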