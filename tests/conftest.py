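import numpy as np
import pytest

from seedsort.preprocess import SpectraMatrix
from seedsort.simulate import SyntheticSpectraSpec, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def raw_spectra(rng):
    """Small raw reflectance matrix spanning beyond the valid range."""
    wl = np.arange(950.0, 2351.0, 6.0)
    base = 0.4 + 0.1 * np.sin(wl / 300.0)
    values = np.clip(base + rng.normal(0, 0.01, (8, wl.size)), 0.01, 0.99)
    return SpectraMatrix(wavelengths=wl, values=values)


@pytest.fixture(scope="session")
def planted_dataset():
    """Paired-capture dataset with a strong planted class signal.

    Coarse 61-band grid keeps model-fitting tests fast while preserving
    the qualitative structure (smooth curves, localized dips, noise).
    """
    spec = SyntheticSpectraSpec(
        n_seeds=120,
        iP=0.6,
        wavelengths=np.linspace(980.0, 2200.0, 61),
    )
    return generate_synthetic_dataset(spec, rng=np.random.default_rng(7))
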