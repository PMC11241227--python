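import numpy as np
import pytest

from mircoag.data_model import Spectra, WavenumberAxis, default_axis
from mircoag.synthetic import default_config, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """Random 5 x 40 spectra on a uniform sub-grid."""
    axis = WavenumberAxis(np.linspace(1000.0, 1400.0, 40))
    matrix = rng.standard_normal((5, 40)) * 0.1 + 0.5
    return Spectra(axis, matrix, [f"S{i}" for i in range(5)])


@pytest.fixture(scope="session")
def full_grid_spectra():
    """Random spectra on the full 1060-point instrument grid (3 samples)."""
    gen = np.random.default_rng(7)
    axis = default_axis()
    return Spectra(axis, gen.standard_normal((3, 1060)) * 0.05 + 0.6, ["a", "b", "c"])


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic dataset, default conditions, n=400 (shared; treat as read-only)."""
    return generate_dataset(default_config(n_samples=400), seed=42)
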