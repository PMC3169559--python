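import numpy as np
import pytest

from lipidorder import (
    CSAComponent,
    OrientationDistribution,
    QuadComponent,
    Spectrum,
    compose,
    csa_axis,
    quad_axis,
)


@pytest.fixture(scope="session")
def sphere() -> OrientationDistribution:
    return OrientationDistribution(epsilon=0.0, n_angles=2048)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def popc_quad_spectrum(sphere):
    """Single broadened doublet: plateau-like splitting of fluid POPC."""
    comp = QuadComponent(splitting_90=29.4, weight=2.0, linewidth=200.0)
    axis = quad_axis(29.4, n=2048)
    return comp, compose([comp], sphere, 0.0, axis)


@pytest.fixture(scope="session")
def popc_csa_spectrum(sphere):
    """Pure-POPC 31P pattern with its fitted anisotropy."""
    comp = CSAComponent(delta_sigma=-47.0, delta_iso=-1.0, linewidth=100.0, weight=1.0, label="PC")
    axis = csa_axis([comp], n=2048, margin=0.35)
    return comp, compose([comp], sphere, 100.0, axis)


@pytest.fixture()
def flat_spectrum():
    axis = np.linspace(-50.0, 50.0, 512)
    return Spectrum(axis, np.ones(512), "2H", 76.0)
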